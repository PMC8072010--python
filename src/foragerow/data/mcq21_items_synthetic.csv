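# Synthetic 21-item monetary choice bank (NOT the published item set).
# Seven geometric implied-k ranks (~0.00016 to ~0.26 per day) crossed with
# three delayed-reward magnitude bins. Amounts in dollars, delays in days.
# Replace this file with any bank sharing these columns to score real data.
item,immediate_amount,delayed_amount,delay_days,magnitude_bin
1,34,35,184,small
2,29,30,63,small
3,27,30,58,small
4,25,30,32,small
5,19,25,14,small
6,24,35,6,small
7,14,25,3,small
8,54,55,116,medium
9,52,55,105,medium
10,54,60,58,medium
11,49,60,36,medium
12,40,55,17,medium
13,34,50,6,medium
14,27,50,3,medium
15,78,80,160,large
16,77,80,71,large
17,67,75,63,large
18,69,85,37,large
19,55,75,17,large
20,54,80,7,large
21,41,75,3,large
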