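ID,TP,FP,FN,TN
GPL10558,52,11,37,118
GPL15207,26,12,11,11
GPL23126,8,0,8,16
GPL570,458,119,187,120
GPL6480,78,2,128,12
GPL96,80,8,188,96
GSE103512,38,2,19,10
GSE113513,14,10,0,4
GSE115261,7,2,3,8
GSE141174,3,0,0,3
GSE151021,3,1,1,3
GSE156355,5,0,1,6
GSE15781,8,2,14,18
GSE20842,45,37,20,28
GSE25071,41,1,5,3
GSE28000,5,4,0,2
GSE35982,4,2,4,6
GSE44076,61,13,37,85
GSE47063,8,1,6,3
GSE62321,16,10,4,8
GSE87211,136,9,67,151
TCGA_GTEx,315,16,156,333
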