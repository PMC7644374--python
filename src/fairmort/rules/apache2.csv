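component,lower,upper,lower_inclusive,upper_inclusive,points
temp,,30,false,false,4
temp,30,32,true,false,3
temp,32,34,true,false,2
temp,34,36,true,false,1
temp,36,38.5,true,false,0
temp,38.5,39,true,false,1
temp,39,41,true,false,3
temp,41,,true,false,4
map,,50,false,false,4
map,50,70,true,false,2
map,70,110,true,false,0
map,110,130,true,false,2
map,130,160,true,false,3
map,160,,true,false,4
hr,,40,false,false,4
hr,40,55,true,false,3
hr,55,70,true,false,2
hr,70,110,true,false,0
hr,110,140,true,false,2
hr,140,180,true,false,3
hr,180,,true,false,4
rr,,6,false,false,4
rr,6,10,true,false,2
rr,10,12,true,false,1
rr,12,25,true,false,0
rr,25,35,true,false,1
rr,35,50,true,false,3
rr,50,,true,false,4
spo2,,86,false,false,4
spo2,86,91,true,false,3
spo2,91,96,true,false,1
spo2,96,,true,false,0
sodium,,111,false,false,4
sodium,111,120,true,false,3
sodium,120,130,true,false,2
sodium,130,150,true,false,0
sodium,150,155,true,false,1
sodium,155,160,true,false,2
sodium,160,180,true,false,3
sodium,180,,true,false,4
potassium,,2.5,false,false,4
potassium,2.5,3,true,false,2
potassium,3,3.5,true,false,1
potassium,3.5,5.5,true,false,0
potassium,5.5,6,true,false,1
potassium,6,7,true,false,3
potassium,7,,true,false,4
creatinine,,0.6,false,false,2
creatinine,0.6,1.5,true,false,0
creatinine,1.5,2,true,false,2
creatinine,2,3.5,true,false,3
creatinine,3.5,,true,false,4
wbc,,1,false,false,4
wbc,1,3,true,false,2
wbc,3,15,true,false,0
wbc,15,20,true,false,1
wbc,20,40,true,false,2
wbc,40,,true,false,4
age,,45,false,false,0
age,45,55,true,false,2
age,55,65,true,false,3
age,65,75,true,false,5
age,75,,true,false,6
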