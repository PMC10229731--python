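%
1	affect
2	posemo
3	negemo
4	anger
5	anxiety
6	sadness
%
angr*	1	3	4
anger*	1	3	4
furious*	1	3	4
fury	1	3	4
irritat*	1	3	4
annoy*	1	3	4
rage	1	3	4
raging	1	3	4
enrag*	1	3	4
resent*	1	3	4
outrag*	1	3	4
mad	1	3	4
livid	1	3	4
frustrat*	1	3	4
indignant	1	3	4
indignation	1	3	4
afraid	1	3	5
scared	1	3	5
scare	1	3	5
scares	1	3	5
anxi*	1	3	5
terrif*	1	3	5
terror	1	3	5
fright*	1	3	5
fear*	1	3	5
nervous*	1	3	5
worr*	1	3	5
panic*	1	3	5
apprehens*	1	3	5
uneas*	1	3	5
unease	1	3	5
alarmed	1	3	5
horrif*	1	3	5
sad	1	3	6
sadly	1	3	6
sadness	1	3	6
sadden*	1	3	6
unhapp*	1	3	6
depress*	1	3	6
miserable	1	3	6
misery	1	3	6
gloom*	1	3	6
heartbr*	1	3	6
sorrow*	1	3	6
grief	1	3	6
griev*	1	3	6
devastat*	1	3	6
deject*	1	3	6
despair*	1	3	6
upset*	1	3	6
lonel*	1	3	6
happy	1	2
happil*	1	2
happin*	1	2
glad*	1	2
joy*	1	2
delight*	1	2
pleased	1	2
pleasure	1	2
pleasing	1	2
cheer*	1	2
excit*	1	2
content*	1	2
proud*	1	2
pride	1	2
grateful	1	2
gratitude	1	2
reliev*	1	2
relief	1	2
elat*	1	2
thrill*	1	2
hopeful	1	2
hoping	1	2
amus*	1	2
surpris*	1
shock*	1	3
asham*	1	3
shame*	1	3
embarrass*	1	3
guilt*	1	3
jealous*	1	3
envious	1	3
envy	1	3
disgust*	1	3
confus*	1	3
overwhelm*	1	3
humiliat*	1	3
bitter*	1	3
stress*	1	3
bored	1	3
boredom	1	3
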