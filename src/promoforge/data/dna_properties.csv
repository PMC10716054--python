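dinucleotide,twist,tilt,roll,shift,slide,rise
AA,0.026,0.038,0.020,1.69,2.26,7.65
AC,0.036,0.038,0.023,1.32,3.03,8.93
AG,0.031,0.037,0.019,1.46,2.03,7.08
AT,0.033,0.036,0.022,1.03,3.83,9.07
CA,0.016,0.025,0.017,1.07,1.78,6.38
CC,0.026,0.042,0.019,1.43,1.65,8.04
CG,0.014,0.026,0.016,1.08,2.00,6.23
CT,0.031,0.037,0.019,1.46,2.03,7.08
GA,0.025,0.038,0.020,1.32,1.93,8.56
GC,0.025,0.036,0.026,1.20,2.61,9.53
GG,0.026,0.042,0.019,1.43,1.65,8.04
GT,0.036,0.038,0.023,1.32,3.03,8.93
TA,0.017,0.018,0.016,0.72,1.20,6.24
TC,0.025,0.038,0.020,1.32,1.93,8.56
TG,0.016,0.025,0.017,1.07,1.78,6.38
TT,0.026,0.038,0.020,1.69,2.26,7.65
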