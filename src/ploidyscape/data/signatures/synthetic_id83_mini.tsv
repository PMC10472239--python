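channel	ID1L	ID2L	ID5L	ID12L	ID8L
1:Del:C:0	0.0000000000	0.0000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:C:1	0.0000000000	0.0000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:C:2	0.0000000000	0.0000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:C:3	0.0000000000	0.0000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:C:4	0.0000000000	0.0800000000	0.0000000000	0.0000000000	0.0000000000
1:Del:C:5	0.0000000000	0.0700000000	0.0000000000	0.0000000000	0.0000000000
1:Del:T:0	0.0000000000	0.0000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:T:1	0.0000000000	0.0000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:T:2	0.0000000000	0.0000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:T:3	0.0000000000	0.1000000000	0.0961538462	0.0000000000	0.0000000000
1:Del:T:4	0.0000000000	0.3000000000	0.0000000000	0.0000000000	0.0000000000
1:Del:T:5	0.0000000000	0.4500000000	0.0000000000	0.0000000000	0.0000000000
1:Ins:C:0	0.0000000000	0.0000000000	0.0384615385	0.0000000000	0.0000000000
1:Ins:C:1	0.0000000000	0.0000000000	0.0384615385	0.0000000000	0.0000000000
1:Ins:C:2	0.0000000000	0.0000000000	0.0384615385	0.0000000000	0.0000000000
1:Ins:C:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
1:Ins:C:4	0.0800000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
1:Ins:C:5	0.0700000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
1:Ins:T:0	0.0000000000	0.0000000000	0.0384615385	0.0000000000	0.0000000000
1:Ins:T:1	0.0000000000	0.0000000000	0.0384615385	0.0000000000	0.0000000000
1:Ins:T:2	0.0000000000	0.0000000000	0.0384615385	0.0000000000	0.0000000000
1:Ins:T:3	0.1000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
1:Ins:T:4	0.3000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
1:Ins:T:5	0.4500000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Del:R:0	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Del:R:1	0.0000000000	0.0000000000	0.0000000000	0.1800000000	0.0000000000
2:Del:R:2	0.0000000000	0.0000000000	0.0000000000	0.1000000000	0.0000000000
2:Del:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Del:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Del:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Del:R:0	0.0000000000	0.0000000000	0.0000000000	0.1400000000	0.0000000000
3:Del:R:1	0.0000000000	0.0000000000	0.0000000000	0.1000000000	0.0000000000
3:Del:R:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Del:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Del:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Del:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Del:R:0	0.0000000000	0.0000000000	0.0000000000	0.1400000000	0.0000000000
4:Del:R:1	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Del:R:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Del:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Del:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Del:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Del:R:0	0.0000000000	0.0000000000	0.0000000000	0.0900000000	0.0000000000
5:Del:R:1	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Del:R:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Del:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Del:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Del:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Ins:R:0	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Ins:R:1	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Ins:R:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Ins:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Ins:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Ins:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Ins:R:0	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Ins:R:1	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Ins:R:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Ins:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Ins:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
3:Ins:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Ins:R:0	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Ins:R:1	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Ins:R:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Ins:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Ins:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Ins:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Ins:R:0	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Ins:R:1	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Ins:R:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Ins:R:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Ins:R:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
5:Ins:R:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
2:Del:M:1	0.0000000000	0.0000000000	0.0000000000	0.1000000000	0.0000000000
3:Del:M:1	0.0000000000	0.0000000000	0.0000000000	0.0800000000	0.0000000000
3:Del:M:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0000000000
4:Del:M:1	0.0000000000	0.0000000000	0.0000000000	0.0700000000	0.0000000000
4:Del:M:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.1000000000
4:Del:M:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.1000000000
5:Del:M:1	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.2000000000
5:Del:M:2	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.2500000000
5:Del:M:3	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.2000000000
5:Del:M:4	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.1000000000
5:Del:M:5	0.0000000000	0.0000000000	0.0000000000	0.0000000000	0.0500000000
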