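participant_id,network,t,value
P00000,SalVentAttnA,0,1.794961252
P00000,SalVentAttnA,1,0.9504568992
P00000,SalVentAttnA,2,-0.6104932336
P00000,SalVentAttnA,3,0.0659090355
P00000,SalVentAttnA,4,1.179577698
P00000,SalVentAttnA,5,-1.239951021
P00000,SalVentAttnA,6,-0.5625808066
P00000,SalVentAttnA,7,0.1011816144
P00000,SalVentAttnB,0,0.2659067953
P00000,SalVentAttnB,1,-0.3804656361
P00000,SalVentAttnB,2,1.418103576
P00000,SalVentAttnB,3,-0.2273362461
P00000,SalVentAttnB,4,0.2514386082
P00000,SalVentAttnB,5,-0.4273083811
P00000,SalVentAttnB,6,1.134200578
P00000,SalVentAttnB,7,0.3925217363
P00000,ContA,0,1.885879515
P00000,ContA,1,0.8115679621
P00000,ContA,2,0.3540515739
P00000,ContA,3,0.5057155643
P00000,ContA,4,-0.5990092014
P00000,ContA,5,-0.1976679593
P00000,ContA,6,1.032995277
P00000,ContA,7,1.017468306
P00000,ContB,0,-0.8427450122
P00000,ContB,1,0.05509514642
P00000,ContB,2,-0.8308785042
P00000,ContB,3,-1.679027089
P00000,ContB,4,0.2084280091
P00000,ContB,5,2.341689603
P00000,ContB,6,0.923888568
P00000,ContB,7,-0.3644637402
P00000,ContC,0,0.3223815575
P00000,ContC,1,-0.8830437685
P00000,ContC,2,-0.1827531924
P00000,ContC,3,-1.316903242
P00000,ContC,4,0.2242555119
P00000,ContC,5,0.3303040595
P00000,ContC,6,-0.6916761613
P00000,ContC,7,0.5150009946
P00000,DefaultA,0,0.1191639608
P00000,DefaultA,1,1.624042069
P00000,DefaultA,2,0.3009981326
P00000,DefaultA,3,0.7901860016
P00000,DefaultA,4,0.2097476974
P00000,DefaultA,5,0.6489444401
P00000,DefaultA,6,-0.838648206
P00000,DefaultA,7,0.07777366444
P00000,DefaultB,0,0.1882369126
P00000,DefaultB,1,0.1032181467
P00000,DefaultB,2,-1.11961856
P00000,DefaultB,3,1.133139853
P00000,DefaultB,4,0.07186904577
P00000,DefaultB,5,0.03859138649
P00000,DefaultB,6,1.080296736
P00000,DefaultB,7,-0.202849735
P00000,DefaultC,0,-0.03670482677
P00000,DefaultC,1,0.5935228941
P00000,DefaultC,2,0.3566786674
P00000,DefaultC,3,0.7197628035
P00000,DefaultC,4,0.8170666929
P00000,DefaultC,5,-0.9573471446
P00000,DefaultC,6,-1.165600836
P00000,DefaultC,7,0.5657324914
P00001,SalVentAttnA,0,1.256542603
P00001,SalVentAttnA,1,-1.081628008
P00001,SalVentAttnA,2,-1.404600441
P00001,SalVentAttnA,3,-2.141122785
P00001,SalVentAttnA,4,0.7931452576
P00001,SalVentAttnA,5,-0.7640528189
P00001,SalVentAttnA,6,-0.4277517501
P00001,SalVentAttnA,7,-1.847965676
P00001,SalVentAttnB,0,0.07945642866
P00001,SalVentAttnB,1,0.1411349006
P00001,SalVentAttnB,2,0.2201533774
P00001,SalVentAttnB,3,-0.00932603264
P00001,SalVentAttnB,4,-2.589972218
P00001,SalVentAttnB,5,-0.1814911485
P00001,SalVentAttnB,6,-0.1233062844
P00001,SalVentAttnB,7,0.3489879503
P00001,ContA,0,-1.491804945
P00001,ContA,1,-0.7088383319
P00001,ContA,2,-1.113686218
P00001,ContA,3,0.5574885388
P00001,ContA,4,-0.05479316509
P00001,ContA,5,-1.969256095
P00001,ContA,6,-0.474838321
P00001,ContA,7,0.2237096647
P00001,ContB,0,-0.4280816229
P00001,ContB,1,-0.527341199
P00001,ContB,2,0.483129048
P00001,ContB,3,-0.7430393148
P00001,ContB,4,0.4457811858
P00001,ContB,5,1.184371937
P00001,ContB,6,0.3623180531
P00001,ContB,7,-0.5812486664
P00001,ContC,0,0.9575778821
P00001,ContC,1,1.255360198
P00001,ContC,2,-1.085086809
P00001,ContC,3,0.04045177054
P00001,ContC,4,1.496215444
P00001,ContC,5,0.0754618843
P00001,ContC,6,0.1901028386
P00001,ContC,7,-0.5559840803
P00001,DefaultA,0,-0.02700758872
P00001,DefaultA,1,0.1563448515
P00001,DefaultA,2,1.190790903
P00001,DefaultA,3,-0.4509043071
P00001,DefaultA,4,1.664314518
P00001,DefaultA,5,0.9791924736
P00001,DefaultA,6,-1.413633596
P00001,DefaultA,7,0.1683408738
P00001,DefaultB,0,0.4931529162
P00001,DefaultB,1,0.3322181582
P00001,DefaultB,2,-0.9804783648
P00001,DefaultB,3,1.800861355
P00001,DefaultB,4,-1.273368534
P00001,DefaultB,5,-1.593644849
P00001,DefaultB,6,-0.867786565
P00001,DefaultB,7,1.015496458
P00001,DefaultC,0,-2.161041063
P00001,DefaultC,1,0.8673639991
P00001,DefaultC,2,0.1320184484
P00001,DefaultC,3,0.5036049924
P00001,DefaultC,4,0.7077414427
P00001,DefaultC,5,0.09790318343
P00001,DefaultC,6,-0.01103691684
P00001,DefaultC,7,-0.4153441297
P00002,SalVentAttnA,0,0.472065799
P00002,SalVentAttnA,1,0.006434712006
P00002,SalVentAttnA,2,0.3008255935
P00002,SalVentAttnA,3,0.02600036893
P00002,SalVentAttnA,4,0.2544090738
P00002,SalVentAttnA,5,-0.2231447989
P00002,SalVentAttnA,6,0.01332078832
P00002,SalVentAttnA,7,-1.152311583
P00002,SalVentAttnB,0,0.4683693403
P00002,SalVentAttnB,1,1.094981321
P00002,SalVentAttnB,2,0.8211466233
P00002,SalVentAttnB,3,0.435260108
P00002,SalVentAttnB,4,-1.741828281
P00002,SalVentAttnB,5,0.1252002127
P00002,SalVentAttnB,6,-1.352966401
P00002,SalVentAttnB,7,-0.1556552103
P00002,ContA,0,0.4108696398
P00002,ContA,1,1.055112894
P00002,ContA,2,0.6753766299
P00002,ContA,3,-1.49635628
P00002,ContA,4,-1.097664528
P00002,ContA,5,-0.3609142287
P00002,ContA,6,-1.352139223
P00002,ContA,7,0.4776293545
P00002,ContB,0,-0.1825824331
P00002,ContB,1,0.9961419998
P00002,ContB,2,-0.1203826959
P00002,ContB,3,-1.159810499
P00002,ContB,4,-0.2716086214
P00002,ContB,5,-3.415022786
P00002,ContB,6,0.1540107774
P00002,ContB,7,-0.06474927813
P00002,ContC,0,0.7376080444
P00002,ContC,1,-1.648991674
P00002,ContC,2,0.497552809
P00002,ContC,3,0.4750346303
P00002,ContC,4,0.6631465553
P00002,ContC,5,0.2686906151
P00002,ContC,6,0.4306732764
P00002,ContC,7,-1.816089841
P00002,DefaultA,0,0.6184997725
P00002,DefaultA,1,0.3730396498
P00002,DefaultA,2,0.1223806602
P00002,DefaultA,3,-0.3236711779
P00002,DefaultA,4,-0.6326577603
P00002,DefaultA,5,0.6378009221
P00002,DefaultA,6,0.5876031053
P00002,DefaultA,7,-0.07297476333
P00002,DefaultB,0,1.158301894
P00002,DefaultB,1,0.5611907641
P00002,DefaultB,2,-0.02866072514
P00002,DefaultB,3,-0.7544055774
P00002,DefaultB,4,-1.107377039
P00002,DefaultB,5,-0.292388464
P00002,DefaultB,6,-0.2255258309
P00002,DefaultB,7,0.6925222528
P00002,DefaultC,0,0.9123400449
P00002,DefaultC,1,0.9650812414
P00002,DefaultC,2,-0.3619063744
P00002,DefaultC,3,0.2992393511
P00002,DefaultC,4,-1.256740576
P00002,DefaultC,5,-0.804391715
P00002,DefaultC,6,0.8833586379
P00002,DefaultC,7,1.174428849
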