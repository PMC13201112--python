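ID,TP,FP,FN,TN
GPL10558,68,12,21,117
GPL15207,32,7,5,16
GPL570,290,56,355,183
GPL6480,188,2,18,12
GPL96,212,24,56,80
GSE103512,53,0,4,12
GSE113513,13,4,1,10
GSE126092,10,1,0,9
GSE141174,3,2,0,1
GSE156355,5,0,1,6
GSE15781,13,3,9,17
GSE20842,64,1,1,64
GSE25071,44,0,2,4
GSE28000,3,1,2,5
GSE44076,69,8,29,90
GSE47063,13,0,1,4
GSE87211,159,13,44,147
TCGA_GTEx,418,26,53,323
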