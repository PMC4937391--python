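subject,hv_time_s,le_time_s,hv_accuracy_pct,le_accuracy_pct,hv_forecast_error_mm,le_forecast_error_mm
1,21,31,80.5,82.4,0.4,0.4
2,53,,73.9,,0.3,
3,21,,80.0,,0.3,
4,19,,87.2,,0.4,
5,26,,71.5,,0.8,
6,33,,82.9,,0.4,
7,30,40,82.9,84.9,0.4,0.3
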