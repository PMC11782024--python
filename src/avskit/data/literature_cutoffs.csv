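region,author,n,comparator,cutoff,sensitivity_pct,specificity_pct,li_convention,si_convention,acth_stimulated,source
left,Wang et al.,222,>=,8.6,19,97,3:1,3:1,True,published
left,This study,54,>=,5.9,27,96,3:1,3:1,True,this_study
left,Kocjan et al.,168,>=,5.9,30,99,4:1,5:1,True,published
left,Strajina et al.,150,>=,5.5,45,82,4:1,5:1,True,published
left,Kocjan et al.,168,>,5.5,32,97,4:1,5:1,True,published
left,Pasternak et al.,36,>,5.5,32,97,4:1,unknown,True,published
left,Lee et al.,121,>=,5.5,34,100,4:1,5:1,True,published
left,Wang et al.,222,>=,5.5,49,89,3:1,3:1,True,published
left,This study,54,>,5.5,33,93,3:1,3:1,True,this_study
left,This study,54,>=,4.4,60,93,3:1,3:1,True,this_study
left,Kocjan et al.,168,>=,4.3,51,95,4:1,5:1,True,published
left,Zibar Tomsic et al.,60,>,3.4,5.8,100,4:1,5:1,True,published
left,Lee et al.,121,>=,3.1,74,82,4:1,5:1,True,published
bilateral,Kocjan et al.,168,<,2.5,70,87,4:1,5:1,True,published
bilateral,Suntornlohanakul et al.,62,<,2.4,64,89,4:1,5:1,True,published
bilateral,This study,54,<,2.4,64,93,3:1,3:1,True,this_study
bilateral,This study,54,<=,1.8,39,100,3:1,3:1,True,this_study
right,Kocjan et al.,168,<,1.25,97,87,4:1,5:1,True,published
right,This study,54,<=,1.2,91,93,3:1,3:1,True,this_study
right,This study,54,<,1.1,91,100,3:1,3:1,True,this_study
right,Lee et al.,121,<,1.0,98,93,4:1,5:1,True,published
right,Kocjan et al.,168,<=,0.5,57,95,4:1,5:1,True,published
right,Kocjan et al.,168,<=,0.5,47,95,4:1,5:1,True,published
right,Strajina et al.,150,<=,0.5,81,100,4:1,5:1,True,published
right,Lee et al.,121,<,0.5,96,96,4:1,5:1,True,published
right,Wang et al.,222,<,0.5,71,95,3:1,3:1,True,published
right,Pasternak et al.,36,<=,0.5,47,95,4:1,unknown,True,published
right,Zibar Tomsic et al.,60,<=,0.37,97.1,88.4,4:1,5:1,True,published
right,Wang et al.,222,<,0.3,71,97,3:1,3:1,True,published
right,Lin et al.,111,<,0.07,40,100,2:1,2:1,False,published
right,Suntornlohanakul et al.,62,<=,0.08,10,99,4:1,5:1,True,published
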