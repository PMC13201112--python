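Cohort,R,p.value,FDR
GSE141174,0.634,0.1760993,0.2340075
GSE156355,0.593,0.04205369,0.07632702
GSE87211,0.544,2.61784E-29,2.22517E-28
TCGA_GTEx,0.481,1.05272E-48,1.78962E-47
GSE103512,0.479,3.08399E-05,8.73796E-05
GSE44076,0.387,2.10083E-08,1.19047E-07
GSE47063,0.324,0.1893323,0.2340075
GSE15781,0.311,0.04489825,0.07632702
GPL10558,0.305,4.61578E-06,1.56937E-05
GPL15207,0.196,0.1336605,0.2065663
GSE113513,0.189,0.3365552,0.3814293
GPL570,0.18,6.83012E-08,2.9028E-07
GPL6480,0.139,0.03873632,0.07632702
GPL96,0.116,0.02530874,0.06146408
GSE25071,-0.028,0.8494591,0.8836653
GSE28000,-0.05,0.8836653,0.8836653
GSE20842,-0.115,0.192712,0.2340075
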