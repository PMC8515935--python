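name,protein_mg,specific_activity
Cell extracts,673.1,0.9
Ammonium sulfate precipitation,201.9,2.4
Phenyl-Sepharose,17.2,18.3
Q-Sepharose,5.0,38.3
DEAE-Sepharose,4.5,41.2
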