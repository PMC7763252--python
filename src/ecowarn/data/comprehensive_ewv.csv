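year,ewv
2011,0.1893
2012,0.2905
2013,0.3505
2014,0.5768
2015,0.7200
2016,0.7774
2017,0.8047
2018,0.8771
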