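trial_id,drug_code,drug_name,class_code,enrollment
METF-01,A10BA02,metformin,A10BA,1138
METF-02,A10BA02,metformin,A10BA,1378
METF-03,A10BA02,metformin,A10BA,756
METF-04,A10BA02,metformin,A10BA,524
METF-05,A10BA02,metformin,A10BA,1012
METF-06,A10BA02,metformin,A10BA,894
METF-07,A10BA02,metformin,A10BA,645
METF-08,A10BA02,metformin,A10BA,535
METF-09,A10BA02,metformin,A10BA,474
METF-10,A10BA02,metformin,A10BA,405
METF-11,A10BA02,metformin,A10BA,2049
METF-12,A10BA02,metformin,A10BA,375
METF-13,A10BA02,metformin,A10BA,1480
METF-14,A10BA02,metformin,A10BA,512
METF-15,A10BA02,metformin,A10BA,1375
GLIB-01,A10BB01,glibenclamide,A10BB,497
GLIP-01,A10BB07,glipizide,A10BB,384
GLIC-01,A10BB09,gliclazide,A10BB,425
GLIC-02,A10BB09,gliclazide,A10BB,622
GLIM-01,A10BB12,glimepiride,A10BB,604
GLIM-02,A10BB12,glimepiride,A10BB,479
GLIM-03,A10BB12,glimepiride,A10BB,428
ROSI-01,A10BG02,rosiglitazone,A10BG,2021
ROSI-02,A10BG02,rosiglitazone,A10BG,987
ROSI-03,A10BG02,rosiglitazone,A10BG,426
ROSI-04,A10BG02,rosiglitazone,A10BG,556
ROSI-05,A10BG02,rosiglitazone,A10BG,706
PIOG-01,A10BG03,pioglitazone,A10BG,4673
PIOG-02,A10BG03,pioglitazone,A10BG,1009
PIOG-03,A10BG03,pioglitazone,A10BG,477
PIOG-04,A10BG03,pioglitazone,A10BG,1139
PIOG-05,A10BG03,pioglitazone,A10BG,920
PIOG-06,A10BG03,pioglitazone,A10BG,1560
PIOG-07,A10BG03,pioglitazone,A10BG,653
PIOG-08,A10BG03,pioglitazone,A10BG,642
SITA-01,A10BH01,sitagliptin,A10BH,1400
SITA-02,A10BH01,sitagliptin,A10BH,2005
SITA-03,A10BH01,sitagliptin,A10BH,2988
SITA-04,A10BH01,sitagliptin,A10BH,907
SITA-05,A10BH01,sitagliptin,A10BH,956
SITA-06,A10BH01,sitagliptin,A10BH,822
SITA-07,A10BH01,sitagliptin,A10BH,1557
SITA-08,A10BH01,sitagliptin,A10BH,511
SITA-09,A10BH01,sitagliptin,A10BH,2162
SITA-10,A10BH01,sitagliptin,A10BH,582
SITA-11,A10BH01,sitagliptin,A10BH,708
SITA-12,A10BH01,sitagliptin,A10BH,1957
SITA-13,A10BH01,sitagliptin,A10BH,3102
SITA-14,A10BH01,sitagliptin,A10BH,3357
SITA-15,A10BH01,sitagliptin,A10BH,527
SITA-16,A10BH01,sitagliptin,A10BH,1610
SITA-17,A10BH01,sitagliptin,A10BH,430
SITA-18,A10BH01,sitagliptin,A10BH,664
VILD-01,A10BH02,vildagliptin,A10BH,513
VILD-02,A10BH02,vildagliptin,A10BH,623
VILD-03,A10BH02,vildagliptin,A10BH,959
VILD-04,A10BH02,vildagliptin,A10BH,676
VILD-05,A10BH02,vildagliptin,A10BH,1507
VILD-06,A10BH02,vildagliptin,A10BH,446
VILD-07,A10BH02,vildagliptin,A10BH,966
VILD-08,A10BH02,vildagliptin,A10BH,441
VILD-09,A10BH02,vildagliptin,A10BH,436
SAXA-01,A10BH03,saxagliptin,A10BH,1102
SAXA-02,A10BH03,saxagliptin,A10BH,1017
SAXA-03,A10BH03,saxagliptin,A10BH,1203
SAXA-04,A10BH03,saxagliptin,A10BH,2205
SAXA-05,A10BH03,saxagliptin,A10BH,734
SAXA-06,A10BH03,saxagliptin,A10BH,1210
SAXA-07,A10BH03,saxagliptin,A10BH,1169
SAXA-08,A10BH03,saxagliptin,A10BH,769
SAXA-09,A10BH03,saxagliptin,A10BH,2322
ALOG-01,A10BH04,alogliptin,A10BH,2433
ALOG-02,A10BH04,alogliptin,A10BH,442
ALOG-03,A10BH04,alogliptin,A10BH,998
ALOG-04,A10BH04,alogliptin,A10BH,660
ALOG-05,A10BH04,alogliptin,A10BH,727
LINA-01,A10BH05,linagliptin,A10BH,617
LINA-02,A10BH05,linagliptin,A10BH,620
LINA-03,A10BH05,linagliptin,A10BH,754
LINA-04,A10BH05,linagliptin,A10BH,579
LINA-05,A10BH05,linagliptin,A10BH,528
LINA-06,A10BH05,linagliptin,A10BH,827
LINA-07,A10BH05,linagliptin,A10BH,1273
GEMI-01,A10BH06,gemigliptin,A10BH,357
GEMI-02,A10BH06,gemigliptin,A10BH,400
EXEN-01,A10BJ01,exenatide,A10BJ,860
EXEN-02,A10BJ01,exenatide,A10BJ,1281
EXEN-03,A10BJ01,exenatide,A10BJ,961
EXEN-04,A10BJ01,exenatide,A10BJ,1439
EXEN-05,A10BJ01,exenatide,A10BJ,2591
EXEN-06,A10BJ01,exenatide,A10BJ,2828
EXEN-07,A10BJ01,exenatide,A10BJ,1165
EXEN-08,A10BJ01,exenatide,A10BJ,2871
EXEN-09,A10BJ01,exenatide,A10BJ,821
EXEN-10,A10BJ01,exenatide,A10BJ,848
EXEN-11,A10BJ01,exenatide,A10BJ,955
LIRA-01,A10BJ02,liraglutide,A10BJ,849
LIRA-02,A10BJ02,liraglutide,A10BJ,669
LIRA-03,A10BJ02,liraglutide,A10BJ,1815
LIRA-04,A10BJ02,liraglutide,A10BJ,444
LIRA-05,A10BJ02,liraglutide,A10BJ,3537
LIRA-06,A10BJ02,liraglutide,A10BJ,5446
LIRA-07,A10BJ02,liraglutide,A10BJ,2269
LIRA-08,A10BJ02,liraglutide,A10BJ,8400
LIRA-09,A10BJ02,liraglutide,A10BJ,2161
LIRA-10,A10BJ02,liraglutide,A10BJ,2571
LIRA-11,A10BJ02,liraglutide,A10BJ,857
LIRA-12,A10BJ02,liraglutide,A10BJ,461
LIRA-13,A10BJ02,liraglutide,A10BJ,606
LIRA-14,A10BJ02,liraglutide,A10BJ,667
LIRA-15,A10BJ02,liraglutide,A10BJ,2901
LIXI-01,A10BJ03,lixisenatide,A10BJ,552
LIXI-02,A10BJ03,lixisenatide,A10BJ,383
LIXI-03,A10BJ03,lixisenatide,A10BJ,1409
LIXI-04,A10BJ03,lixisenatide,A10BJ,440
DULA-01,A10BJ05,dulaglutide,A10BJ,5263
DULA-02,A10BJ05,dulaglutide,A10BJ,549
DULA-03,A10BJ05,dulaglutide,A10BJ,748
DULA-04,A10BJ05,dulaglutide,A10BJ,1062
DULA-05,A10BJ05,dulaglutide,A10BJ,1287
DULA-06,A10BJ05,dulaglutide,A10BJ,1634
DULA-07,A10BJ05,dulaglutide,A10BJ,3320
SEMA-01,A10BJ06,semaglutide,A10BJ,618
SEMA-02,A10BJ06,semaglutide,A10BJ,871
SEMA-03,A10BJ06,semaglutide,A10BJ,1269
SEMA-04,A10BJ06,semaglutide,A10BJ,1053
SEMA-05,A10BJ06,semaglutide,A10BJ,2661
SEMA-06,A10BJ06,semaglutide,A10BJ,2250
SEMA-07,A10BJ06,semaglutide,A10BJ,1074
SEMA-08,A10BJ06,semaglutide,A10BJ,689
DAPA-01,A10BK01,dapagliflozin,A10BK,1087
DAPA-02,A10BK01,dapagliflozin,A10BK,1609
DAPA-03,A10BK01,dapagliflozin,A10BK,2354
DAPA-04,A10BK01,dapagliflozin,A10BK,820
DAPA-05,A10BK01,dapagliflozin,A10BK,3265
DAPA-06,A10BK01,dapagliflozin,A10BK,586
DAPA-07,A10BK01,dapagliflozin,A10BK,2460
DAPA-08,A10BK01,dapagliflozin,A10BK,2044
CANA-01,A10BK02,canagliflozin,A10BK,3301
CANA-02,A10BK02,canagliflozin,A10BK,777
CANA-03,A10BK02,canagliflozin,A10BK,622
CANA-04,A10BK02,canagliflozin,A10BK,871
CANA-05,A10BK02,canagliflozin,A10BK,1036
CANA-06,A10BK02,canagliflozin,A10BK,1213
CANA-07,A10BK02,canagliflozin,A10BK,2193
EMPA-01,A10BK03,empagliflozin,A10BK,506
EMPA-02,A10BK03,empagliflozin,A10BK,1172
EMPA-03,A10BK03,empagliflozin,A10BK,1236
EMPA-04,A10BK03,empagliflozin,A10BK,1252
EMPA-05,A10BK03,empagliflozin,A10BK,536
EMPA-06,A10BK03,empagliflozin,A10BK,507
EMPA-07,A10BK03,empagliflozin,A10BK,2095
EMPA-08,A10BK03,empagliflozin,A10BK,4542
ERTU-01,A10BK04,ertugliflozin,A10BK,926
ERTU-02,A10BK04,ertugliflozin,A10BK,3159
ERTU-03,A10BK04,ertugliflozin,A10BK,374
ERTU-04,A10BK04,ertugliflozin,A10BK,1482
ERTU-05,A10BK04,ertugliflozin,A10BK,885
NATE-01,A10BX03,nateglinide,A10BX,404
NATE-02,A10BX03,nateglinide,A10BX,360
TASP-01,A10BX90,taspoglutide,A10BX,449
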