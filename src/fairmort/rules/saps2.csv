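component,lower,upper,lower_inclusive,upper_inclusive,points
hr,,40,false,false,11
hr,40,70,true,false,2
hr,70,120,true,false,0
hr,120,160,true,false,4
hr,160,,true,false,7
sbp,,70,false,false,13
sbp,70,100,true,false,5
sbp,100,200,true,false,0
sbp,200,,true,false,2
temp,,39,false,false,0
temp,39,,true,false,3
gcs,,6,false,false,26
gcs,6,9,true,false,13
gcs,9,11,true,false,7
gcs,11,14,true,false,5
gcs,14,,true,false,0
wbc,,1,false,false,12
wbc,1,20,true,false,0
wbc,20,,true,false,3
potassium,,3,false,false,3
potassium,3,5,true,false,0
potassium,5,,true,false,3
sodium,,125,false,false,5
sodium,125,145,true,false,0
sodium,145,,true,false,1
age,,40,false,false,0
age,40,60,true,false,7
age,60,70,true,false,12
age,70,75,true,false,15
age,75,80,true,false,16
age,80,,true,false,18
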