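%
1	function
2	pronoun_i
3	pronoun_we
4	certain
5	tentat
6	cause
7	negemo
8	posemo
9	health
10	ingest
11	social
12	assent
13	cogproc
14	focuspast
15	money
%
the	1
a	1
an	1
of	1
to	1
and	1
in	1
that	1
is	1
was	1	14
i	2
me	2
my	2
mine	2
we	3
us	3
our	3
ours	3
always	4
never	4
absolutely	4
certainly	4
definitely	4
proven	4	13
guaranteed	4
undeniable	4
every	4
all	4
maybe	5
perhaps	5
possibly	5
might	5
seems	5
appear*	5
suggest*	5	13
tentative*	5
somewhat	5
caus*	6	13
because	6	13
effect*	6	13
consequen*	6
therefore	6
hence	6
result*	6
hate	7
angry	7
afraid	7
terrible	7
horrible	7
toxic	7
danger*	7
fear*	7
worry	7
harm*	7
love	8
great	8
good	8
wonderful	8
amazing	8
benefi*	8
hope*	8
safe	8
clinic*	9
flu	9
pill*	9
doctor*	9
hospital*	9
medic*	9
vaccin*	9
symptom*	9
dose*	9
therap*	9
dish	10
eat*	10
pizza	10
food*	10
diet*	10
drink*	10
nutri*	10
swallow*	10
friend*	11
famil*	11
mother*	11
father*	11
child*	11
parent*	11
talk*	11	14
neighbor*	11
agree*	12
ok	12
okay	12
yes	12
absolutely	12
know	13
ought	13
think*	13
understand*	13
reason*	13
believ*	13
ago	14
did	14
were	14
had	14
cash	15
money	15
price*	15
cheap*	15
afford*	15
cost*	15
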