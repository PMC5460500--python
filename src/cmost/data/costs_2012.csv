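kind,item,stage,phase,value
procedure,colonoscopy,,,885
procedure,polypectomy,,,245
procedure,sigmoidoscopy,,,348
procedure,fobt,,,23
complication,major_bleed,,,6650
complication,minor_bleed,,,1250
complication,mucosal_burn,,,2660
complication,perforation,,,15680
treatment,crc,1,initial,20000
treatment,crc,2,initial,28000
treatment,crc,3,initial,34000
treatment,crc,4,initial,40000
treatment,crc,1,continuing,1800
treatment,crc,2,continuing,2200
treatment,crc,3,continuing,3000
treatment,crc,4,continuing,7000
treatment,crc,1,terminal,32000
treatment,crc,2,terminal,36000
treatment,crc,3,terminal,40000
treatment,crc,4,terminal,47000
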