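conformer,ELE,VDW,INT,PBSUR,PBCAL,TS
Open,-6853.7,-1611.3,7864.4,760.8,-4564.9,-4151.1
Semi-closed,-6766.4,-1616.2,7875.6,768.4,-4664.7,-4150.9
STE,1.9,0.3,0.4,0.2,1.7,1.2
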