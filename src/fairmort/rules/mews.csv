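component,lower,upper,lower_inclusive,upper_inclusive,points
sbp,,71,false,false,3
sbp,71,81,true,false,2
sbp,81,101,true,false,1
sbp,101,200,true,false,0
sbp,200,,true,false,2
hr,,41,false,false,2
hr,41,51,true,false,1
hr,51,101,true,false,0
hr,101,111,true,false,1
hr,111,130,true,false,2
hr,130,,true,false,3
rr,,9,false,false,2
rr,9,15,true,false,0
rr,15,21,true,false,1
rr,21,30,true,false,2
rr,30,,true,false,3
temp,,35,false,false,2
temp,35,38.5,true,false,0
temp,38.5,,true,false,2
avpu,,1,false,false,0
avpu,1,2,true,false,1
avpu,2,3,true,false,2
avpu,3,,true,false,3
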