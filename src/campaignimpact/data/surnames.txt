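smith
johnson
brown
garcia
miller
davis
rodriguez
martinez
hernandez
lopez
gonzalez
wilson
anderson
jackson
martin
lee
perez
thompson
white
harris
sanchez
clark
ramirez
lewis
robinson
walker
young
allen
king
wright
torres
nguyen
hill
flores
green
adams
nelson
baker
hall
rivera
campbell
mitchell
carter
roberts
lanteri
suarez
mejova
okafor
tanaka
kowalski
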