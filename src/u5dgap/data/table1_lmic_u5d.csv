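# Country summary of under-five deaths (U5D) by sex, most recent DHS 2010-2018.
# One row per country (is_region_aggregate=0) plus regional subtotal rows and a
# grand-total row (is_region_aggregate=1).  Rates are deaths per 1000 live
# births, stored exactly as published (integers; pct_male to one decimal).
# sig_flag=1 marks a published footnote: z-test of equality of male/female
# proportions significant at 0.05.  Run-together digits in the published layout
# were resolved against the journal table during transcription; every row was
# cross-checked so that country n_children and n_clusters sum to the printed
# regional and overall totals (856,987 children; 66,495 clusters).
country,region,survey_year,n_children,n_clusters,pct_male,u5d_overall,u5d_male,u5d_female,sig_flag,is_region_aggregate
Eastern Africa,Eastern Africa,,109945,6298,50.7,52,57,47,1,1
Burundi,Eastern Africa,2011,13192,554,50.5,59,62,55,0,0
Comoros,Eastern Africa,2012,3149,252,50.7,42,44,40,0,0
Ethiopia,Eastern Africa,2016,10641,643,51.9,55,67,42,1,0
Kenya,Eastern Africa,2014,20964,1593,50.8,44,46,42,0,0
Malawi,Eastern Africa,2016,17286,850,50.1,49,55,42,1,0
Mozambique,Eastern Africa,2011,11102,610,50.6,74,79,70,0,0
Rwanda,Eastern Africa,2014,7856,492,50.4,39,43,34,1,0
Tanzania,Eastern Africa,2015,10233,608,50.7,53,57,48,1,0
Uganda,Eastern Africa,2016,15522,696,50.4,51,58,44,1,0
Middle Africa,Middle Africa,,76790,2932,50.5,70,77,64,1,1
Angola,Middle Africa,2016,14322,625,49.8,51,58,45,1,0
Cameroon,Middle Africa,2018,9733,429,51.5,62,67,56,1,0
Chad,Middle Africa,2015,18623,624,51.2,98,108,88,1,0
Congo,Middle Africa,2012,9329,384,49.6,51,57,46,1,0
Congo DR,Middle Africa,2014,18716,536,49.7,75,77,72,0,0
Gabon,Middle Africa,2012,6067,334,51.8,53,63,43,1,0
Northern Africa,Northern Africa,,15848,876,52.7,24,26,22,0,1
Egypt,Northern Africa,2014,15848,876,52.7,24,26,22,0,0
Southern Africa,Southern Africa,,27823,2549,49.9,51,55,46,1,1
Lesotho,Southern Africa,2014,3138,397,49.5,69,70,69,0,0
Namibia,Southern Africa,2013,5046,537,48.8,45,46,44,0,0
South Africa,Southern Africa,2016,3548,671,52.1,36,42,30,0,0
Zambia,Southern Africa,2018,9959,545,50.2,49,56,42,1,0
Zimbabwe,Southern Africa,2015,6132,399,49.1,57,63,50,1,0
Western Africa,Western Africa,,147996,6099,50.8,81,86,75,1,1
Benin,Western Africa,2018,13589,555,51.0,70,78,62,1,0
Burkina Faso,Western Africa,2010,15044,573,50.7,89,94,85,1,0
Cote d'Ivoire,Western Africa,2013,7776,351,50.3,84,108,60,1,0
Gambia,Western Africa,2013,8088,281,50.7,41,41,40,0,0
Ghana,Western Africa,2014,5884,427,52.2,46,50,43,0,0
Guinea,Western Africa,2018,7951,401,51.9,87,89,83,0,0
Liberia,Western Africa,2013,7606,322,51.1,70,70,70,0,0
Mali,Western Africa,2018,9940,345,50.8,72,74,69,0,0
Niger,Western Africa,2012,12558,476,50.5,81,84,77,0,0
Nigeria,Western Africa,2018,33924,1389,50.9,97,100,93,1,0
Senegal,Western Africa,2018,6719,214,50.9,40,48,32,1,0
Sierra Leone,Western Africa,2013,11938,435,50.0,113,120,107,1,0
Togo,Western Africa,2013,6979,330,50.4,63,68,57,0,0
Central Asia,Central Asia,,10558,682,50.9,28,30,26,0,1
Kyrgyz Rep,Central Asia,2012,4363,316,51.2,26,23,30,0,0
Tajikistan,Central Asia,2017,6195,366,50.8,29,35,24,1,0
South-Eastern Asia,South-Eastern Asia,,17716,1851,51.5,26,28,24,0,1
Cambodia,South-Eastern Asia,2014,7165,609,50.1,29,31,26,0,0
Philippines,South-Eastern Asia,2017,10551,1242,52.5,24,25,23,0,0
Southern Asia,Southern Asia,,338925,33064,52.0,44,46,41,1,1
Afghanistan,Southern Asia,2015,32712,956,51.6,47,49,45,0,0
Bangladesh,Southern Asia,2014,7886,600,52.1,41,39,43,0,0
India,Southern Asia,2016,259627,28332,52.2,44,47,41,1,0
Indonesia,Southern Asia,2017,17848,1967,51.1,27,32,23,1,0
Maldives,Southern Asia,2016,3106,265,50.9,18,21,15,0,0
Nepal,Southern Asia,2016,5038,383,52.3,34,32,37,0,0
Pakistan,Southern Asia,2018,12708,561,50.2,66,74,58,1,0
Western Asia,Western Asia,,28475,2050,51.6,33,36,29,1,1
Armenia,Western Asia,2016,1724,306,53.3,5,4,6,0,0
Jordan,Western Asia,2017,10658,964,51.6,17,19,16,0,0
Yemen,Western Asia,2013,16093,780,51.4,45,50,40,1,0
Central America,Central America,,23328,1996,52.1,28,30,26,0,1
Guatemala,Central America,2014,12440,856,51.9,31,34,28,0,0
Honduras,Central America,2011,10888,1140,52.4,25,26,24,0,0
South America,South America,,21379,4788,50.7,16,17,15,0,1
Colombia,South America,2015,11759,3386,50.4,15,16,13,0,0
Peru,South America,2012,9620,1402,51.1,17,19,16,0,0
Southern Europe,Southern Europe,,6410,688,52.1,10,9,10,0,1
Albania,Southern Europe,2018,2762,652,51.1,4,6,2,0,0
Turkey,Southern Europe,2013,3648,36,52.8,14,12,17,0,0
Caribbean,Caribbean,,22280,1863,51.5,47,51,42,1,1
Dominican Rep,Caribbean,2013,3714,518,51.7,29,33,25,0,0
Haiti,Caribbean,2016,6530,450,50.3,69,74,64,0,0
Myanmar,Caribbean,2015,4815,440,52.2,44,48,40,0,0
Timor Leste,Caribbean,2016,7221,455,52.0,37,41,33,0,0
Oceania,Oceania,,9514,759,52.5,40,40,40,0,1
Papua NG,Oceania,2016,9514,759,52.5,40,40,40,0,0
Total,All,,856987,66495,51.4,51,55,48,1,1
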