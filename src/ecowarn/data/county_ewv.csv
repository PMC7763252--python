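region,year,ewv,esl
MH,2011,0.3460,II
MH,2012,0.3311,II
MH,2013,0.3361,II
MH,2014,0.3917,II
MH,2015,0.3952,II
MH,2016,0.4220,III
MH,2017,0.4491,III
MH,2018,0.4273,III
PA,2011,0.5441,III
PA,2012,0.5308,III
PA,2013,0.5549,III
PA,2014,0.6220,IV
PA,2015,0.5675,III
PA,2016,0.5996,III
PA,2017,0.6354,IV
PA,2018,0.6448,IV
HZ,2011,0.3377,II
HZ,2012,0.3957,II
HZ,2013,0.4218,III
HZ,2014,0.4037,III
HZ,2015,0.4584,III
HZ,2016,0.4495,III
HZ,2017,0.4766,III
HZ,2018,0.4761,III
XH,2011,0.3992,II
XH,2012,0.3737,II
XH,2013,0.3680,II
XH,2014,0.3836,II
XH,2015,0.3991,II
XH,2016,0.4002,III
XH,2017,0.3937,II
XH,2018,0.4237,III
HL,2011,0.3187,II
HL,2012,0.2966,II
HL,2013,0.2918,II
HL,2014,0.3371,II
HL,2015,0.3959,II
HL,2016,0.3905,II
HL,2017,0.4075,III
HL,2018,0.3967,II
LD,2011,0.3868,II
LD,2012,0.4344,III
LD,2013,0.4461,III
LD,2014,0.5343,III
LD,2015,0.6179,IV
LD,2016,0.6050,IV
LD,2017,0.6116,IV
LD,2018,0.6290,IV
HZh,2011,0.3913,II
HZh,2012,0.4157,III
HZh,2013,0.4345,III
HZh,2014,0.5320,III
HZh,2015,0.5761,III
HZh,2016,0.5845,III
HZh,2017,0.5838,III
HZh,2018,0.6008,IV
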