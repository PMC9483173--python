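threshold,group,method,dataset,reported_BA,reported_SE,reported_SP,reported_MCC,reported_AUC,TP,FP,TN,FN
6,single,BRF,VS,0.87,0.92,0.81,0.58,0.95,226,250,1088,19
6,single,GB,VS,0.82,0.68,0.96,0.68,0.94,170,52,1286,75
6,single,KNN,VS,0.84,0.72,0.96,0.70,0.91,176,51,1287,69
6,single,MLP,VS,0.76,0.56,0.96,0.57,0.89,136,54,1284,109
6,single,XGB,VS,0.84,0.73,0.95,0.69,0.94,179,60,1278,66
6,single,SVM,VS,0.84,0.72,0.96,0.69,0.93,176,58,1280,69
6,single,(S)RF,VS,0.85,0.73,0.96,0.72,0.95,178,46,1292,67
6,single,(S)GB,VS,0.83,0.72,0.95,0.66,0.82,177,72,1266,68
6,single,(S)KNN,VS,0.86,0.86,0.85,0.59,0.92,214,209,1129,31
6,single,(S)MLP,VS,0.81,0.86,0.76,0.48,0.91,211,322,1016,34
6,single,(S)XGB,VS,0.78,0.74,0.82,0.46,0.87,181,239,1099,64
6,single,(S)SVM,VS,0.88,0.91,0.85,0.62,0.89,223,198,1140,22
5,single,BRF,VS,0.83,0.85,0.82,0.67,0.92,655,147,663,114
5,single,GB,VS,0.83,0.84,0.82,0.66,0.92,646,147,663,123
5,single,KNN,VS,0.83,0.84,0.82,0.66,0.91,647,151,659,122
5,single,MLP,VS,0.80,0.83,0.77,0.60,0.88,640,192,618,129
5,single,XGB,VS,0.83,0.84,0.82,0.65,0.91,643,150,660,126
5,single,SVM,VS,0.83,0.86,0.80,0.66,0.91,659,163,647,110
5,single,(S)RF,VS,0.83,0.84,0.82,0.67,0.92,645,143,673,118
5,single,(S)GB,VS,0.83,0.84,0.82,0.64,0.92,637,147,672,123
5,single,(S)KNN,VS,0.82,0.86,0.78,0.64,0.90,652,178,641,108
5,single,(S)MLP,VS,0.77,0.84,0.69,0.65,0.85,645,143,665,126
5,single,(S)XGB,VS,0.84,0.85,0.83,0.68,0.90,681,136,647,115
5,single,(S)SVM,VS,0.84,0.84,0.84,0.68,0.91,650,130,678,121
6,consensus,(S)SVM+(S)KNN,VS,0.91,0.93,0.90,0.72,0.93,207,117,1048,15
6,consensus,(S)SVM+(S)KNN,ES,0.72,0.66,0.77,0.34,0.73,55,107,365,29
6,consensus,BRF+(S)SVM,VS,0.91,0.95,0.87,0.69,0.95,215,153,1043,11
6,consensus,BRF+(S)SVM,ES,0.71,0.60,0.81,0.33,0.72,53,102,454,35
6,consensus,BRF+(S)KNN,VS,0.91,0.94,0.88,0.68,0.95,208,152,1031,13
6,consensus,BRF+(S)KNN,ES,0.72,0.68,0.76,0.33,0.73,53,112,348,25
5,consensus,BRF+SVM,VS,0.87,0.89,0.86,0.75,0.93,619,108,608,74
5,consensus,BRF+SVM,ES,0.72,0.67,0.76,0.43,0.75,220,67,212,107
5,consensus,BRF+GB,VS,0.87,0.88,0.86,0.74,0.93,618,104,622,86
5,consensus,BRF+GB,ES,0.70,0.66,0.74,0.41,0.73,216,71,212,120
5,consensus,SVM+GB,VS,0.87,0.88,0.86,0.74,0.93,614,103,603,78
5,consensus,SVM+GB,ES,0.71,0.66,0.75,0.41,0.74,223,69,213,116
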