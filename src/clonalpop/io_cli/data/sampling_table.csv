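label,temperature_c,salinity_ppt,ph,oxygen_mg_l,obtained,sequenced
April 2009,12,14,ND,ND,0,0
June 2009,16,14,ND,ND,0,0
Aug 2009,19,14,ND,ND,6,6
Oct 2009,7,15,ND,ND,7,7
Nov 2009,7,15,ND,ND,4,4
Feb 2010,0.5,ND,ND,ND,0,0
June 2011,17,12,ND,ND,0,0
Aug 2011,18,13,ND,ND,11,11
Sep 2011,15,11,ND,ND,0,0
Aug 2012,20,14,ND,ND,4,4
Sep 2012,16,14,ND,ND,14,14
Aug 2014,ND,ND,ND,ND,13,9
Sep 2018,16,15,ND,2.27,19,19
Oct 2019,9,14,7.98,2.48,0,0
July 2020,17,14,ND,ND,9,8
Aug 2020,22,15,8.51,2.23,23,19
Sep 2020,21,14,8.26,4.28,11,11
May 2021,13,ND,8.18,ND,0,0
July 2021,ND,ND,ND,ND,ND,ND
Sep 2021,ND,ND,ND,ND,ND,ND
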