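demonym	country
japanese	Japan
chinese	China
american	United States
indian	India
italian	Italy
korean	South Korea
turkish	Turkey
indonesian	Indonesia
german	Germany
french	France
british	United Kingdom
english	United Kingdom
spanish	Spain
brazilian	Brazil
mexican	Mexico
thai	Thailand
vietnamese	Vietnam
iranian	Iran
egyptian	Egypt
greek	Greece
polish	Poland
russian	Russia
swedish	Sweden
norwegian	Norway
danish	Denmark
finnish	Finland
dutch	Netherlands
belgian	Belgium
swiss	Switzerland
austrian	Austria
portuguese	Portugal
irish	Ireland
israeli	Israel
saudi	Saudi Arabia
pakistani	Pakistan
bangladeshi	Bangladesh
nepalese	Nepal
srilankan	Sri Lanka
armenian	Armenia
argentine	Argentina
chilean	Chile
colombian	Colombia
peruvian	Peru
canadian	Canada
australian	Australia
tunisian	Tunisia
moroccan	Morocco
algerian	Algeria
nigerian	Nigeria
kenyan	Kenya
ethiopian	Ethiopia
malaysian	Malaysia
filipino	Philippines
taiwanese	Taiwan
mongolian	Mongolia
czech	Czech Republic
slovak	Slovakia
hungarian	Hungary
romanian	Romania
bulgarian	Bulgaria
croatian	Croatia
serbian	Serbia
ukrainian	Ukraine
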