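# synthetic golden reference: S(qz, qpar) by dense direct quadrature
# (no table/interpolation shortcuts); eta=0.1 xi=60 d=53 Lr=1200 sr=400 Lz=530 sz=106, no beam smearing
# row 0: qpar axis; col 0: qz axis
0 0 0.014285714 0.028571429 0.042857143 0.057142857 0.071428571 0.085714286 0.1 0.11428571 0.12857143 0.14285714 0.15714286 0.17142857 0.18571429 0.2
0.3 3.699627e+10 2.1314619e+10 1.1046421e+10 4.7198897e+09 2.0268401e+09 9.3228845e+08 4.6365589e+08 2.473743e+08 1.3977397e+08 82460181 50010528 30604106 18449041 10545893 5314624.7
0.375 5.5586351e+10 3.3756697e+10 1.5051713e+10 6.5813829e+09 3.0520583e+09 1.4990834e+09 7.7788818e+08 4.2500402e+08 2.4300567e+08 1.4415502e+08 87746383 54041330 33047841 19485094 10448311
0.45 2.7734711e+10 2.1980455e+10 1.3101569e+10 7.0872761e+09 3.7867522e+09 2.0488303e+09 1.1354769e+09 6.4841626e+08 3.8218236e+08 2.3210862e+08 1.4460696e+08 91792522 58817898 37560288 23443705
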