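compound,type,split,pIC50,reference_pred
1,I,train,8.699,
2,I,train,7.276,
3,I,train,7.114,
4,I,train,6.523,
5,I,train,6.071,
6,I,train,6.420,
7,I,train,8.222,
8,I,test,8.097,
9,I,train,9.523,
10,I,test,8.699,
11,I,train,8.523,
12,I,train,8.699,
13,I,train,7.796,
14,I,train,8.398,
15,I,test,8.097,
16,I,train,8.301,
17,II,train,8.523,
18,III,train,8.155,
19,III,train,7.523,
20,IV,test,6.398,
21,IV,train,7.046,
22,IV,train,6.523,
T1,I,theoretical,,8.651
T2,I,theoretical,,8.172
T3,I,theoretical,,7.876
T4,I,theoretical,,7.388
T5,I,theoretical,,6.908
T6,III,theoretical,,6.668
T7,III,theoretical,,7.208
T8,III,theoretical,,6.904
T9,III,theoretical,,6.617
T10,IV,theoretical,,6.248
T11,IV,theoretical,,6.102
T12,IV,theoretical,,6.100
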