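term	variants	category
angry	anger,angrily,angered	anger
furious	fury,furiously	anger
irritated	irritation,irritating	anger
annoyed	annoyance,annoying	anger
enraged	rage,raging	anger
resentful	resentment	anger
outraged	outrage	anger
mad		anger
livid		anger
frustrated	frustration,frustrating	anger
indignant	indignation	anger
afraid		anxiety
scared	scare,scares	anxiety
anxious	anxiety,anxiously	anxiety
terrified	terror,terrifying	anxiety
frightened	fright,frightening	anxiety
fearful	fear,fears	anxiety
nervous	nervousness,nervously	anxiety
worried	worry,worries,worrying	anxiety
panicked	panic,panicky	anxiety
apprehensive	apprehension	anxiety
uneasy	unease	anxiety
alarmed		anxiety
horrified	horrifying	anxiety
sad	sadness,sadly,saddened	sadness
unhappy	unhappiness	sadness
depressed	depression,depressing	sadness
miserable	misery	sadness
gloomy	gloom	sadness
heartbroken	heartbreak	sadness
sorrowful	sorrow	sadness
grieved	grief,grieving	sadness
devastated	devastating	sadness
dejected	dejection	sadness
despairing	despair	sadness
upset	upsetting	sadness
lonely	loneliness	sadness
happy	happily,happiness	positive
glad	gladly	positive
joyful	joy,joyous	positive
delighted	delight,delightful	positive
pleased	pleasure,pleasing	positive
cheerful	cheery	positive
excited	excitement,exciting	positive
contented	contentment	positive
proud	pride,proudly	positive
grateful	gratitude	positive
relieved	relief	positive
elated	elation	positive
thrilled		positive
hopeful	hoping	positive
amused	amusement	positive
surprised	surprise,surprising	other_affect
shocked	shock,shocking	other_affect
ashamed	shame,shameful	other_affect
embarrassed	embarrassment,embarrassing	other_affect
guilty	guilt	other_affect
jealous	jealousy	other_affect
envious	envy	other_affect
disgusted	disgust,disgusting	other_affect
confused	confusion	other_affect
overwhelmed		other_affect
humiliated	humiliation	other_affect
bored	boredom	other_affect
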