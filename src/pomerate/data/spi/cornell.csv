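# Placeholder table for the 'cornell' starch pattern index card.
# Scores are evenly spaced stand-ins: replace the score column with values
# read off your own card images before production use.
category,score
1,100.0
2,85.71
3,71.43
4,57.14
5,42.86
6,28.57
7,14.29
8,0.0
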