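# words counted as subjective (opinion/evaluation markers)
good
great
excellent
wonderful
amazing
love
best
happy
bad
terrible
horrible
awful
hate
worst
scary
useless
fake
miracle
believe
think
feel
opinion
seems
maybe
perhaps
surely
definitely
absolutely
never
always
should
must
incredible
shocking
outrageous
dubious
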