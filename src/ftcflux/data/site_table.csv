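site_id,latitude,longitude,igbp,elevation,mat,map
AT-Neu,47.1167,11.3175,GRA,970,6.5,852
BE-Lon,50.5516,4.7462,CRO,167,10.0,800
BE-Vie,50.3049,5.9981,MF,493,7.8,1062
CA-Gro,48.2167,-82.1556,MF,340,1.3,831
CA-Oas,53.6289,-106.198,DBF,530,0.3,428.53
CA-TP4,42.7102,-80.3574,ENF,184,8.0,1036
CH-Lae,47.4783,8.3644,MF,689,8.3,1100
CH-Oe2,47.2864,7.7337,CRO,452,9.8,1155
DE-Hai,51.0792,10.4522,DBF,430,8.3,720
DE-Kli,50.8931,13.5224,CRO,478,7.6,842
DE-Tha,50.9626,13.5651,ENF,385,8.2,843
DK-Sor,55.4859,11.6446,DBF,40,8.2,660
FI-Hyy,61.8474,24.2948,ENF,181,3.8,709
FI-Sod,67.3624,26.6386,ENF,180,-1.0,500
IT-Lav,45.9562,11.2813,ENF,1353,7.8,1291
IT-Ren,46.5869,11.4337,ENF,1730,4.7,809.3
US-ARM,36.6058,-97.4888,CRO,314,14.76,843
US-Me2,44.4526,-121.5589,ENF,1253,6.28,523
US-MMS,39.3232,-86.4131,DBF,275,10.85,1032
US-NR1,40.0329,-105.546,ENF,3050,1.5,800
US-Oho,41.5545,-83.8438,DBF,230,10.1,849
US-Syv,46.242,-89.3477,MF,540,3.81,826
US-UMB,45.5598,-84.7138,DBF,234,5.83,803
US-WCr,45.8059,-90.0799,DBF,520,4.02,787
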