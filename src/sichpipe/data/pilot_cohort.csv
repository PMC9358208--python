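id,sex,age,pmhx,ich_site,icu_days,cmo_day,death_day,ich_score,mrs_90d,fcm_day,gcs,iph_vol,phe_vol,mgs,nlr,rogue_n_count,net_n_count
1,F,71,HT,Thalamus,39,,,2,5,4,7,5.52,14.07,13,5.7,2571,640
2,M,67,unknown,Thalamus,16,16,16,2,6,4,12,13.87,13.92,9,17.3,4017,663
3,F,82,HT,Thalamus,7,7,7,3,6,2,13,17.82,12.75,13,5.6,2470,822
4,M,60,HT,Thalamus,6,,,1,3,3,15,0.71,3.78,12,4.2,285,89
5,M,71,HT,Cor. radiata,7,4,5,3,6,2,7,1.57,4.86,21,10.1,5950,3343
6,F,83,NT,Occ. Par.,11,6,11,4,6,5,10,44.70,48.40,1,5.6,5072,4645
7,M,51,HT,Occ. Par.,6,,,0,2,4,15,0.77,1.93,0,1.5,909,519
8,F,60,HT,Thalamus,19,,,2,5,8,9,6.09,11.91,4,3.0,2140,1252
9,F,83,NT,Thalamus,2,,,1,3,2,14,2.92,0.77,0,1.4,950,651
10,M,63,HT,Thalamus,10,,,2,5,0,6,25.20,19.90,13,8.6,4590,1260
11,F,71,NT,Basal Ganglia,2,,,1,3,1,14,0.63,2.47,12,1.6,1050,573
12,M,32,HT,Thalamus,39,,,2,3,4,12,1.89,1.89,9,2.7,282,213
13,M,37,HT,Basal Ganglia,4,,,0,0,3,14,12.60,8.40,1,1.9,935,655
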