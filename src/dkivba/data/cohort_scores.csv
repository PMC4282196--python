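subject_id,group,sex,age,education_years,cias,sas,sds,bis_attentional,bis_motor,bis_nonplanning,bis_total
IGA1,IGA,M,20,14,64,64,61,19,24,28,71
IGA2,IGA,M,14,12,65,56,54,18,22,26,66
IGA3,IGA,M,19,12,64,61,59,12,17,23,52
IGA4,IGA,M,15,8,66,54,61,12,17,22,51
IGA5,IGA,F,22,12,76,58,48,14,17,25,56
IGA6,IGA,M,17,9,83,50,54,19,24,29,72
IGA7,IGA,M,22,16,84,51,49,13,16,27,56
IGA8,IGA,M,18,10,75,46,61,15,18,31,64
IGA9,IGA,M,23,11,87,56,68,23,24,29,76
IGA10,IGA,M,23,12,81,59,36,23,23,27,73
IGA11,IGA,M,22,12,65,30,56,13,22,26,61
IGA12,IGA,M,24,13,64,44,34,15,20,26,61
IGA13,IGA,M,16,10,75,70,70,15,33,27,65
IGA14,IGA,M,22,12,86,68,40,20,27,33,80
IGA15,IGA,M,27,11,76,43,50,16,22,26,64
IGA16,IGA,F,24,10,78,48,56,16,24,24,64
IGA17,IGA,F,23,11,82,58,60,16,22,27,65
IGA18,IGA,M,18,10,69,50,61,15,14,25,54
CON1,control,F,25,11,32,31,28,11,13,19,43
CON2,control,M,18,9,39,41,46,13,20,21,54
CON3,control,F,26,9,30,39,33,10,17,19,46
CON4,control,M,27,9,26,40,38,12,13,19,44
CON5,control,M,23,11,50,55,44,18,16,26,60
CON6,control,M,21,13,26,29,28,10,11,16,37
CON7,control,M,21,13,52,36,35,13,18,25,56
CON8,control,M,22,14,32,34,39,10,15,19,44
CON9,control,M,22,14,51,46,46,19,18,26,63
CON10,control,M,21,14,34,35,33,10,18,18,46
CON11,control,M,18,9,31,46,38,11,18,20,49
CON12,control,F,23,16,50,48,45,18,18,26,62
CON13,control,M,22,15,47,41,39,12,15,25,52
CON14,control,M,24,15,44,30,28,12,17,19,48
CON15,control,M,23,14,40,35,39,10,19,22,51
CON16,control,M,22,14,32,28,33,15,16,22,53
CON17,control,M,22,12,42,46,44,14,16,22,52
CON18,control,M,19,12,28,43,34,10,17,15,42
CON19,control,M,19,12,28,53,44,11,18,30,59
CON20,control,M,20,12,47,48,46,12,14,25,51
CON21,control,M,23,12,46,56,50,15,20,20,55
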