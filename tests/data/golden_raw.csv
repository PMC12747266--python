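smiles,target_chembl_id,standard_value,standard_units,standard_type
c1ccc(SC)cc1,CHEMBL204,6275.562770409227,nM,IC50
c1cc(CCC)cc(N(C)C)c1,CHEMBL204,353549.7846902187,nM,IC50
C1CCC(O)C1,CHEMBL204,0.04936422178198055,uM,IC50
c1cc(NC)cnc1S,CHEMBL203,247.4441175514113,nM,IC50
c1cc(OC(=O)C)oc1,CHEMBL203,101.67382789214435,nM,IC50
C1CCC(C#N)CC1,CHEMBL204,1107.6762187038205,nM,IC50
c1cc(SC)cc(Cl)c1,CHEMBL206,1558.166116967622,uM,IC50
c1nc(F)cc(OC)n1,CHEMBL203,59.28343195528724,nM,IC50
c1ccc(Cl)nc1,CHEMBL204,0.9557624529421858,uM,IC50
c1cc(CCO)cnc1Br,CHEMBL203,3.9657345743925814,uM,IC50
c1cc(N(C)C)ccc1F,CHEMBL203,3574.544808037001,nM,IC50
C1CCC(CC(C)O)CC1,CHEMBL206,25.410126451156913,uM,IC50
C1CCC(N)CC1,CHEMBL203,18.78236350066374,nM,IC50
c1ccc(OC)cc1,CHEMBL203,2.0801644964114656,uM,IC50
CC(N)C(=O)O,CHEMBL206,0.8475334945507295,nM,IC50
c1cc(CC(C)O)ncn1,CHEMBL203,113.7363503418084,nM,IC50
C1CCC(O)CC1,CHEMBL204,0.3659831170746825,uM,IC50
c1cc(CCO)oc1NC,CHEMBL206,4046.8091612441904,nM,IC50
c1cc(NC)oc1CCC,CHEMBL204,29791.415009407945,nM,IC50
C1CCC(F)CC1,CHEMBL203,2.470278669572919,uM,IC50
c1cc(F)cnc1O,CHEMBL203,110.60185849356206,nM,IC50
c1nc(N(C)C)cc(Br)n1,CHEMBL203,1656.9968040636536,nM,IC50
c1cc(CO)ncn1,CHEMBL203,4.234194996089039,nM,IC50
C1CC(O)CC(Br)C1,CHEMBL203,2.4375933881653697,uM,IC50
c1ccc(CCO)cc1,CHEMBL203,160.33542836611508,nM,IC50
c1cc(S)ccc1CO,CHEMBL206,7.048249257745417,uM,IC50
c1nc(CC(C)O)cc(CC(C)O)n1,CHEMBL204,870.6141851793234,nM,IC50
c1cc(C#N)cc(SC)c1,CHEMBL203,4.4351479335410655,uM,IC50
c1cc(CCO)oc1OC(=O)C,CHEMBL206,1400.9499156884146,nM,IC50
c1ccc(C(F)(F)F)cc1,CHEMBL203,8029.484518579337,nM,IC50
c1nc(C(F)(F)F)cc(CC)n1,CHEMBL203,4759.77906914004,nM,IC50
c1cc(OC(=O)C)cc(OC(=O)C)c1,CHEMBL206,4.232136704183187,uM,IC50
c1ccc(CC)nc1,CHEMBL203,749.1213934334017,nM,IC50
c1nc(F)cc(OC)n1,CHEMBL203,0.053932166446127285,uM,IC50
c1cc(F)oc1F,CHEMBL204,367.91460692086537,nM,IC50
C1CCC(CCO)CC1,CHEMBL204,10481.949068966867,nM,IC50
C1CC(I)CC(C(=O)O)C1,CHEMBL204,91135.54905957158,nM,IC50
c1ccc(NC)nc1,CHEMBL204,205.48639056955298,nM,IC50
C1CCC(I)C1,CHEMBL203,18353.309549316888,nM,IC50
c1cc(OC)cc(NC)c1,CHEMBL204,3.1945431886753317,uM,IC50
c1cc(I)ncn1,CHEMBL204,3476.6334204722575,nM,IC50
C1CCC(I)C1,CHEMBL203,23773.74804799002,nM,IC50
C1CC(CO)CC(F)C1,CHEMBL204,1999.7825348711792,nM,IC50
CC(=O)NCCO,CHEMBL203,0.0013578719896217605,uM,IC50
c1cc(S)sc1,CHEMBL206,14158.177558786907,nM,IC50
c1cc(CC)sc1,CHEMBL206,23470.505790426618,nM,IC50
c1cc(CCO)oc1,CHEMBL204,446.1540213737948,nM,IC50
c1cc(N)cnc1C,CHEMBL204,0.03590379165460656,uM,IC50
C1CCC(Br)CC1,CHEMBL203,10290.030157093765,nM,IC50
c1cc(OC(=O)C)cnc1N(C)C,CHEMBL204,1056.3566504598848,nM,IC50
c1cc(C(=O)O)ccc1F,CHEMBL204,1466.7497511262209,nM,IC50
CCO,CHEMBL203,0.0,nM,IC50
c1cc(Br)oc1,CHEMBL203,1652.1710214588595,nM,IC50
c1cc(C#N)sc1,CHEMBL203,0.527102681868538,uM,IC50
C1CCC(F)CC1,CHEMBL203,2180.7995812687063,nM,IC50
c1nc(I)cc(Cl)n1,CHEMBL204,4361.1890275414735,nM,IC50
C1CCC(CCC)C1,CHEMBL204,107.38240818038166,uM,IC50
C1CCC(CC)C1,CHEMBL206,81240.57578328089,nM,IC50
c1ccc(C)cc1,CHEMBL206,5636.315874372452,nM,IC50
C1CC(C#N)CC(CC(C)O)C1,CHEMBL203,1912.5309171293763,nM,IC50
c1cc(NC)ccc1C(F)(F)F,CHEMBL203,16357.834018292016,nM,IC50
c1cc(O)oc1,CHEMBL204,35.92289888806962,nM,IC50
C1CC(OC(=O)C)CC(C(C)C)C1,CHEMBL203,8352.402832338294,nM,IC50
c1ccc2cc(CO)ccc2c1,CHEMBL206,60106.89698942373,nM,IC50
c1ccc(I)nc1,CHEMBL203,5795.349340901396,nM,IC50
c1cc(C(=O)O)cc(CCC)c1,CHEMBL204,6809.504236788988,nM,IC50
c1cc(NC)ccc1O,CHEMBL203,0.14674668772065047,uM,IC50
CC(=O)NC,CHEMBL203,1.5296368610616227,nM,IC50
CCN,CHEMBL203,100.0,,IC50
c1cc(CCO)oc1OC(=O)C,CHEMBL206,1622.1351668810146,nM,IC50
CCC(NC)CO,CHEMBL203,16.910177484632403,nM,IC50
c1cc(F)cc(CCO)c1,CHEMBL203,1.4044583970508409,uM,IC50
c1cc(NC)ccc1O,CHEMBL203,0.09478613361639365,uM,IC50
c1cc(F)sc1,CHEMBL203,412.3858863295928,nM,IC50
c1cc(CO)oc1C,CHEMBL204,179.23567976352726,nM,IC50
c1cc(F)oc1F,CHEMBL204,0.44715903277711916,uM,IC50
c1cc(NC)ccc1C(F)(F)F,CHEMBL203,14212.816290292465,nM,IC50
c1ccc(CC)cc1,CHEMBL203,2492.284343514676,nM,IC50
C1CCC(OC)CC1,CHEMBL203,1963.4823261777976,nM,IC50
c1cc(CC(C)O)oc1CC(C)O,CHEMBL204,5621.5887514628,nM,IC50
CCC,CHEMBL203,100.0,nM,Ki
c1ccc(N(C)C)nc1,CHEMBL206,3674.274399611818,nM,IC50
c1cc(Br)ccc1O,CHEMBL203,1413.3968815883334,nM,IC50
C1CC(S)CC(I)C1,CHEMBL204,340974.037145679,nM,IC50
c1cc(C(F)(F)F)oc1O,CHEMBL206,17488.634716231198,nM,IC50
C1CCC(Br)C1,CHEMBL204,11.117639641773943,uM,IC50
c1cc(Cl)oc1,CHEMBL204,0.9231778180529748,uM,IC50
C1CC(,CHEMBL204,100.0,nM,IC50
C1CC(,CHEMBL206,100.0,nM,IC50
C1CC(I)CC(N)C1,CHEMBL204,7812.267096560543,nM,IC50
c1ccc2cc(CC)ccc2c1,CHEMBL203,64.47470816301873,uM,IC50
CCO,CHEMBL206,0.0,nM,IC50
c1nc(N(C)C)cc(Br)n1,CHEMBL203,1298.7948827457715,nM,IC50
c1ccc(C#N)cc1,CHEMBL204,698.6943766155684,nM,IC50
CCC,CHEMBL203,100.0,nM,Ki
c1cc(CCC)ccc1OC(=O)C,CHEMBL206,340.38045893853865,uM,IC50
c1cc(OC)cc(OC)c1,CHEMBL203,2.553246498948967,uM,IC50
c1cc(C)oc1CC,CHEMBL204,7341.209814008069,nM,IC50
c1cc(NC)ncn1,CHEMBL203,0.03357417206175637,uM,IC50
c1cc(S)ncn1,CHEMBL204,0.11160486201489808,uM,IC50
CCN,CHEMBL203,100.0,,IC50
c1ccc(CCC)cc1,CHEMBL206,222451.84959301865,nM,IC50
c1cc(Br)cnc1C(=O)O,CHEMBL204,2.155483221389151,uM,IC50
c1cc(NC)ccc1N(C)C,CHEMBL203,4928.76356254856,nM,IC50
c1cc(Br)cnc1C(F)(F)F,CHEMBL203,35194.31318595312,nM,IC50
c1cc(CO)cc(Cl)c1,CHEMBL203,991.8332642305047,nM,IC50
c1nc(C#N)cc(Br)n1,CHEMBL204,0.3412409711181382,uM,IC50
c1cc(CC)ncn1,CHEMBL204,0.4743141231543058,uM,IC50
c1ccc(CCC)nc1,CHEMBL203,4629.5662407130685,nM,IC50
c1ccc(C(C)C)cc1,CHEMBL204,58166.7424451271,nM,IC50
c1cc(NC)cc(C(=O)O)c1,CHEMBL206,9774.892310152885,nM,IC50
c1cc(S)ccc1CO,CHEMBL206,7412.369374108903,nM,IC50
c1cc(C#N)oc1,CHEMBL203,10.800732439009822,nM,IC50
CCN,CHEMBL203,100.0,,IC50
c1cc(CCC)ccc1F,CHEMBL204,66126.6829019275,nM,IC50
c1nc(SC)cc(S)n1,CHEMBL206,7808.808886015631,nM,IC50
c1cc(O)sc1,CHEMBL203,55.288789753346556,nM,IC50
c1ccc2cc(SC)ccc2c1,CHEMBL206,1510406.7893921956,nM,IC50
c1cc(CCO)ncn1,CHEMBL204,0.06297842776653684,uM,IC50
c1ccc2cc(CC)ccc2c1,CHEMBL203,90185.49312670363,nM,IC50
CC(C)(C)O,CHEMBL203,7.180795182010508,nM,IC50
CCO,CHEMBL204,0.0,nM,IC50
C1CC(OC(=O)C)CC(C(C)C)C1,CHEMBL203,9.87519822993866,uM,IC50
c1ccc(S)nc1,CHEMBL203,577.804802758211,nM,IC50
CCC,CHEMBL204,100.0,nM,Ki
c1ccc2cc(I)ccc2c1,CHEMBL203,369818.5256118239,nM,IC50
C1CC(,CHEMBL206,100.0,nM,IC50
C1CCC(C(C)C)CC1,CHEMBL203,18285.34000634343,nM,IC50
CCCC(=O)O,CHEMBL203,10.222610215630198,nM,IC50
c1ccc(N(C)C)cc1,CHEMBL204,2576.0028688429506,nM,IC50
C1CC(SC)CC(CC)C1,CHEMBL203,63614.86967693978,nM,IC50
c1cc(Br)ccc1CO,CHEMBL203,1.6153509260684131,uM,IC50
c1cc(S)ncn1,CHEMBL204,116.89583896788919,nM,IC50
CCOCC,CHEMBL203,320.80951609045667,nM,IC50
c1cc(F)oc1N(C)C,CHEMBL203,2.133143868579075,uM,IC50
c1cc(I)cnc1CCC,CHEMBL206,1129980.6728313793,nM,IC50
C1CC(O)CC(CC)C1,CHEMBL203,1798.39369436236,nM,IC50
c1cc(Br)ccc1O,CHEMBL203,2226.3720496950314,nM,IC50
c1cc(CC)oc1,CHEMBL203,1278.130050343617,nM,IC50
c1cc(C(F)(F)F)ncn1,CHEMBL204,1559.0722925445737,nM,IC50
C1CCC(CCC)C1,CHEMBL204,68595.11135753796,nM,IC50
c1ccc2cc(OC)ccc2c1,CHEMBL203,24.17557264143126,uM,IC50
c1cc(OC(=O)C)ncn1,CHEMBL203,0.0085234164097187,uM,IC50
c1cc(CCC)cc(S)c1,CHEMBL203,23.838525797771517,uM,IC50
c1nc(C(C)C)cc(Cl)n1,CHEMBL203,3.9806775623023936,uM,IC50
c1cc(O)ccc1C(C)C,CHEMBL203,2.2952237061175627,uM,IC50
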