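claplepra
stortaplol
prolin
glelaice
gliafocain
drital
bridos
buclian
cagraigeth
zaibis
caidrul
brebriaran
cligain
brorstebri
diacaster
liskezain
skorpriar
momugan
tavaflal
praiflorth
ralul
clorzulil
glupriatiar
driaskemin
taifostus
stiakugaix
gukuzir
plolar
droprorx
fupevor
loglugron
bepaith
draplin
vupai
noflial
florniaflur
niaskian
giflal
glaitrisko
praireskix
storvubar
griazostal
metai
traipriax
skobair
storsumoth
fulorl
trornux
godiar
nobiagle
kiglin
claiskais
regail
zogail
viatrestu
feviglorr
brorbeskal
tiatur
cusaidail
glorgrin
kiamaikir
kiakiagu
porrorvai
fliacairul
metasoth
torfial
maclul
tragagrus
stiaroth
porstormiax
mobretith
baglus
kefor
gridral
cornaiclain
zorflial
plulus
truglosun
flasozix
graiskair
kekor
piacluglors
naiburiar
torlen
preskail
badorfith
vekia
greraith
torex
rornailith
mapekais
zaiploraith
miabrinor
clinaigluth
zorziath
futeprul
flusix
raikoth
prucluth
capriavorr
grociagrorn
steprux
torbaiporr
riatath
trimas
pestaino
plocil
vaibrin
ziabreth
forskaitun
druprigorx
baclegil
triastaikel
flotrian
gortredrol
ritais
vatrar
tailainaix
pezabi
ripraflas
glortror
daisuth
pliavoli
bripriax
plordria
fabrodras
nogaix
kivaiclai
ziakopair
drusadath
zigupla
trorgruskex
stecefliax
ciacaigra
zorbro
gregeth
clugaiteth
cigreskith
vorlordro
clortedoth
laiskorl
cubrorl
clifle
mokeflaix
vafusti
briapokiath
doplax
puclorskail
siamian
stabiax
raplus
flavas
feduclar
ludra
praiflaflia
drumico
prenian
viavaix
skobiclor
greprorx
diavuth
biasar
cevox
buclial
skotias
bobri
rucanex
triprorforr
ciadel
rorles
sazex
drorbaiclux
rordusiax
cliborskors
glozedrun
triaces
zorzisoth
pliraidail
skadors
vusiakol
skedri
corlacol
paroth
laigruskor
dagrurar
prigon
gluriagrin
groken
brosaix
skagareth
staibais
drugra
kailon
tropripreth
rivor
droclordoth
dreskeglias
maitaipria
kiduth
glialocles
trorplavor
stepraiprul
fliaglair
kofetial
digis
peglorl
pagrain
prolors
prianen
viriavia
glimiaskiar
bailex
forclepail
baigriku
curavix
stavoth
doglapol
glesticli
pruplorr
skiabrorzen
skiliacla
mivus
kaitol
lucan
skimair
norzas
traidia
claipox
laigevai
skutobaith
prisifuth
tripepar
drordrial
skevor
datai
pavorn
gastorflir
fliaclaith
bordrisus
briakiax
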