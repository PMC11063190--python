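site,kind,initiation,peak,termination,duration_days,mean_chl,max_chl
Amvrakikos Gulf,coastal,07–13 Nov,02–08 Jan,14–20 May,189,4.744,7.835
Thermaikos Gulf,coastal,09–15 Jan,19–25 Mar,11–17 Jun,154,2.373,5.332
Alexandroupolis Gulf,coastal,14–20 Nov,26 Mar–01 Apr,04–10 Jun,203,1.117,3.173
Maliakos Gulf,coastal,03–09 Oct,19–25 Dec,09–15 Apr,189,1.117,3.181
Gulf of Kavala,coastal,07–13 Nov,20–26 Feb,07–13 May,182,0.614,1.701
South Evoikos Gulf,coastal,17–23 Oct,16–22 Jan,02–08 Apr,196,0.516,1.625
Gulf of Patras,coastal,17–23 Oct,19–25 Dec,09–15 Apr,175,0.394,0.921
Pagasitikos Gulf,coastal,31 Oct–06 Nov,02–08 Jan,09–15 Apr,161,0.234,0.546
Gulf of Corinth,coastal,24–30 Oct,12–18 Mar,21–27 May,210,0.230,0.699
Saronikos Gulf,coastal,17–23 Oct,20–26 Feb,09–15 Apr,175,0.159,0.327
Laganas Gulf,coastal,24–30 Oct,06–12 Feb,09–15 Apr,168,0.089,0.109
Gulf of Heraklion,coastal,17–23 Oct,16–22 Jan,16–22 Apr,182,0.075,0.162
North Aegean Sea,open_sea,21–27 Nov,26 Mar–01 April,28 May–03 Jun,189,0.212,0.399
Central Aegean Sea,open_sea,24–30 Oct,12–18 Mar,09–15 Apr,168,0.088,0.143
Myrtoan Sea,open_sea,24–30 Oct,20–26 Feb,09–15 Apr,168,0.071,0.114
Rhodes Gyre,open_sea,14–20 Nov,27 Feb–04 Mar,23–29 Apr,161,0.067,0.185
Cyclades,open_sea,31 Oct–06 Nov,27 Feb–04 Mar,09–15 Apr,161,0.069,0.095
Cretan Sea,open_sea,07–13 Nov,13–19 Feb,16–22 Apr,161,0.060,0.091
Pelops Gyre,open_sea,31 Oct–06 Nov,20–26 Feb,16–22 Apr,161,0.055,0.081
Ierapetra Gyre,open_sea,31 Oct–06 Nov,20–26 Feb,16–22 Apr,161,0.049,0.082
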