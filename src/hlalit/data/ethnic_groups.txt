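han
european
asian
african
caucasian
hispanic
latino
arab
jewish
ashkenazi
sephardic
berber
kurdish
roma
basque
sami
inuit
maori
aboriginal
amerindian
mestizo
creole
afro-american
african-american
bantu
zulu
yoruba
igbo
tamil
bengali
punjabi
sinhalese
uyghur
tibetan
mongol
hmong
javanese
malay
polynesian
melanesian
micronesian
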