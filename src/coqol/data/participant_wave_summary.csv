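wave,ipaq_score,mspss_score,gads_score,predimed_score,selfmna_score,mfe_score,psqi_score,eq5d_vas,energy_kcal,steps,heart_rate_bpm,sedentary_min,sedentary_light_min,light_min,light_fair_min,fair_min,fair_vigorous_min,vigorous_min,active_min,sleep
1,,5,68,7,12,13,15,80,2044.0,8035.0,52.5,842.0,999.0,192.5,253.0,23.0,51.0,19.0,300.0,7:06
2,7338,5,51,5,,15,15,75,1889.0,6076.0,56.0,843.0,994.0,207.0,245.0,21.0,51.5,22.5,273.5,7:08
3,21702,5,47,7,12,8,14,80,1979.0,8172.0,55.0,798.0,975.0,204.0,248.0,40.0,70.0,33.0,294.0,7:03
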