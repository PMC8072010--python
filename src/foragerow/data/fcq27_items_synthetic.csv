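# Synthetic 27-item food choice bank (NOT the published item set).
# Amounts are hypothetical bites of one's favorite food, delays in days;
# nine implied-k ranks crossed with three magnitude bins, mirroring the
# structure of the canonical 27-item monetary questionnaire.
# Replace this file with any bank sharing these columns to score real data.
item,immediate_amount,delayed_amount,delay_days,magnitude_bin
1,34,35,186,small
2,28,30,179,small
3,22,25,136,small
4,25,30,80,small
5,19,25,53,small
6,24,35,29,small
7,14,25,19,small
8,15,35,13,small
9,11,30,7,small
10,54,55,117,medium
11,47,50,160,medium
12,54,60,111,medium
13,49,60,89,medium
14,40,55,62,medium
15,34,50,30,medium
16,27,50,21,medium
17,25,60,14,medium
18,20,55,7,medium
19,78,80,162,large
20,80,85,157,large
21,67,75,119,large
22,69,85,91,large
23,55,75,61,large
24,54,80,30,large
25,41,75,20,large
26,33,80,14,large
27,31,85,7,large
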