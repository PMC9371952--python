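# word<TAB>polarity score in [-1, 1]
good	0.7
great	0.8
excellent	1.0
wonderful	0.9
amazing	0.8
love	0.8
safe	0.5
beneficial	0.6
effective	0.5
helpful	0.6
miracle	0.9
best	1.0
happy	0.8
bad	-0.7
terrible	-0.9
horrible	-1.0
awful	-0.9
hate	-0.8
toxic	-0.8
dangerous	-0.7
harmful	-0.7
deadly	-1.0
poison	-0.9
worst	-1.0
scary	-0.6
risky	-0.5
useless	-0.6
fake	-0.6
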