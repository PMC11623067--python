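name,out_h,out_w,out_c,params,kernel,filters,growth
Base_Conv1,224,224,32,896,3x3,32,32
B1_HL_Conv1,112,112,64,2112,1x1,64,96
B1_HL_Conv2,112,112,64,18496,3x3,64,160
B1_HL_Conv3,112,112,64,51264,5x5,64,224
B1_HL_Conv4,112,112,64,100416,7x7,64,288
B1_HL_Conv5,112,112,256,590080,3x3,256,544
B1_HL_Conv6,112,112,256,590080,3x3,256,800
B1_HL_Conv7,112,112,512,1180160,3x3,512,1312
B1_LL_Conv1,112,112,64,18496,3x3,64,1376
Base_Conv2,56,56,576,2986560,3x3,576,1952
B2_HL_Conv1,28,28,64,36928,1x1,64,2016
B2_HL_Conv2,28,28,64,331840,3x3,64,2080
B2_HL_Conv3,28,28,64,921664,5x5,64,2144
B2_HL_Conv4,28,28,64,1806400,7x7,64,2208
B2_HL_Conv5,28,28,256,590080,3x3,256,2464
B2_HL_Conv6,28,28,256,590080,3x3,256,2720
B2_HL_Conv7,28,28,512,1180160,3x3,512,3232
B2_LL_Conv1,28,28,64,331840,3x3,64,3296
Base_Conv3,14,14,576,2986560,3x3,576,3872
# total_params,14331331
# trainable_params,14323587
# non_trainable_params,7744
# total_feature_maps,3872
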