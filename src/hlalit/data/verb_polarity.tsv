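lemma	class
associate	positive
link	positive
correlate	positive
confer	positive
relate	positive
predispose	positive
increase	positive
elevate	positive
enhance	positive
contribute	positive
implicate	positive
involve	positive
predict	positive
cause	positive
induce	positive
carry	positive
influence	positive
mediate	positive
promote	positive
predetermine	positive
protect	negative
decrease	negative
reduce	negative
lower	negative
resist	negative
prevent	negative
investigate	investigatory
study	investigatory
examine	investigatory
evaluate	investigatory
assess	investigatory
explore	investigatory
determine	investigatory
analyze	investigatory
analyse	investigatory
compare	investigatory
characterize	investigatory
screen	investigatory
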