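year,area_class,area_ha,agb_t,carbon_tC
2007,degraded,992,10371,4874
2007,restored,140,12030,5654
2007,retained,2793,259710,122064
2007,Total,3925,282110,132592
2018,degraded,143,5776,2715
2018,restored,865,22325,10493
2018,retained,2917,315558,148312
2018,Total,3925,343660,161520
2028,degraded,123,3200,1504
2028,restored,1112,73012,34316
2028,retained,2690,351677,165288
2028,Total,3925,427889,201108
2038,degraded,108,2561,1204
2038,restored,1251,99659,46840
2038,retained,2566,388158,182434
2038,Total,3925,490378,247475
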