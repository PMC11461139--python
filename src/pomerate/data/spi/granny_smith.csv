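# Placeholder table for the 'granny_smith' starch pattern index card.
# Scores are evenly spaced stand-ins: replace the score column with values
# read off your own card images before production use.
category,score
1,100.0
2,80.0
3,60.0
4,40.0
5,20.0
6,0.0
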