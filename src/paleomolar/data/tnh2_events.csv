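# Independent age estimates for the Tam Ngu Hao 2 sequence (kyr, 1 sigma).
# unit 0 = lower silty clay (LU1), unit 1 = fossil-bearing breccia (LU2),
# unit 2 = overlying flowstone (minimum age for the breccia below).
label,age_kyr,sigma_kyr,role,unit,method
LCC3,248,31,direct,0,pIR-IRSL
LCC1,143,24,direct,1,pIR-IRSL
LCC2,133,19,direct,1,pIR-IRSL
TNH2-10/CC10,164,24,direct,1,US-ESR
TNH2-11/CC11,149,22,direct,1,US-ESR
TNH2-12/CC12,140,23,direct,1,US-ESR
CCF1,104,27,minimum,2,U-series
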