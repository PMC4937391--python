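subject,forecast_error_mean_mm,forecast_error_sd_mm,prediction_accuracy_mean_pct,prediction_accuracy_sd_pct
1,0.4,0.3,80.5,10.3
2,0.3,0.3,73.9,19.9
3,0.3,0.2,80.0,13.8
4,0.4,0.2,87.2,27.2
5,0.8,0.7,71.5,15.8
6,0.4,0.5,82.9,18.4
7,0.4,0.2,82.9,10.7
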