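subject,sex,age_at_7t,disease_duration_yrs,left_plic_volume_mm3,right_plic_volume_mm3
ET001,M,70,49,4694,5133
ET002,F,66,5,3946,4034
ET003,M,65,1,3561,4338
ET004,M,41,17,5293,5170
ET005,M,73,5,4679,4934
ET006,M,67,26,4762,4492
ET007,F,73,30,4072,4286
ET008,M,55,21,4519,5042
ET009,F,73,2,5215,5109
ET010,F,64,33-43,5584,4833
ET011,M,70,4,4914,5654
ET012,M,72,20,5002,5205
ET013,F,63,4,3546,3811
ET014,M,42,4,5480,5168
ET015,F,72,23-33,3539,3317
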