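name,pKi,set
aldosterone,6.28,train
androstanediol,5,train
androstenediol,5,train
androstenedione,5.76,train
androsterone,5.61,train
corticosterone,7.88,train
cortisol,7.88,train
cortisone,6.89,train
dehydroepiandrostrone,5,train
deoxycorticosterone,7.65,train
deoxycortisol,7.88,train
dihydrotestosterone,5.92,train
estradiol,5,train
estriol,5,train
estrone,5,train
etiocholanolone,5.26,train
pregnenolone,5.26,train
hydroxypregnenlone,5,train
progesterone,7.38,train
hydroxyprog,7.74,train
testosterone,6.72,train
prednisolone,7.51,test
cortisol-21-acetate,7.55,test
4-pregnene-3-11-20-trione,6.78,test
epicorticosterone,7.2,test
19-nortestosterone,6.14,test
16a-17-dihydroxy-4-pregnene-3-20-dione,6.25,test
16a-methyl-4-pregnene-3-20-dione,7.12,test
19-norprogesterone,6.82,test
11b-17-21-trihydroxy-2a-methyl-4-pregnen-3-20-dione,7.69,test
11b-17-21-trihydroxy-2a-methyl-9a-fluoro-4-pregnen-3-20-dione,5.8,test
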