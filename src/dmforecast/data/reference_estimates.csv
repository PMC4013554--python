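source,year,group,prevalence_pct
IDF (2011),2011,total,16.2
IDF (2011),2030,total,20.8
GBD (2011),2000,male,17.5
GBD (2011),2000,female,17.7
GBD (2011),2008,male,22.0
GBD (2011),2008,female,21.7
Shaw et al.,2010,total,13.6
Shaw et al.,2030,total,17.0
Wild et al.,2000,total,6.2
Wild et al.,2030,total,8.1
King et al.,1995,total,8.7
King et al.,2000,total,9.1
King et al.,2025,total,10.1
Amos et al.,1995,total,10.0
Amos et al.,2000,total,12.0
Amos et al.,2010,total,13.8
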