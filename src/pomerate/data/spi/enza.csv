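# Placeholder table for the 'enza' starch pattern index card.
# Scores are evenly spaced stand-ins: replace the score column with values
# read off your own card images before production use.
category,score
1,100.0
2,83.33
3,66.67
4,50.0
5,33.33
6,16.67
7,0.0
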