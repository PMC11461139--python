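# Placeholder table for the 'jonagold' starch pattern index card.
# Scores are evenly spaced stand-ins: replace the score column with values
# read off your own card images before production use.
category,score
1,100.0
2,90.0
3,80.0
4,70.0
5,60.0
6,50.0
7,40.0
8,30.0
9,20.0
10,10.0
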