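landmark,predicted_displacement_mm,measured_displacement_mm,forecast_error_mm,prediction_accuracy_pct
1,2.0,2.9,0.9,66.9
2,1.8,2.0,0.2,91.7
3,1.6,2.2,0.7,70.4
4,1.2,1.5,0.3,82.5
5,2.2,2.3,0.2,92.9
6,1.5,2.2,0.7,68.8
7,1.3,1.0,0.4,63.8
8,2.1,2.2,0.1,94.8
9,2.3,2.5,0.2,92.2
10,2.5,2.8,0.3,88.2
11,1.5,1.8,0.3,84.9
12,2.1,2.9,0.8,72.3
13,1.7,2.2,0.5,78.6
14,1.1,0.9,0.2,79.0
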