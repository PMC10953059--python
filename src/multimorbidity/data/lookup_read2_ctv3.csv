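source_code,source_framework,target_code
B011.,READ2,YB011
B011.,READ2,ZB011
B012.,READ2,YB012
B013.,READ2,YB013
C021.,READ2,YC021
C021.,READ2,ZC021
C022.,READ2,YC022
C023.,READ2,YC023
D031.,READ2,YD031
D031.,READ2,ZD031
D032.,READ2,YD032
D033.,READ2,YD033
E041.,READ2,YE041
E041.,READ2,ZE041
E043.,READ2,YE043
F051.,READ2,YF051
F051.,READ2,ZF051
F052.,READ2,YF052
F053.,READ2,YF053
G061.,READ2,YG061
G061.,READ2,ZG061
G062.,READ2,YG062
G063.,READ2,YG063
H071.,READ2,YH071
H071.,READ2,ZH071
H072.,READ2,YH072
H073.,READ2,YH073
J092.,READ2,YJ092
J093.,READ2,YJ093
K101.,READ2,YK101
K101.,READ2,ZK101
K102.,READ2,YK102
K103.,READ2,YK103
L111.,READ2,YL111
L111.,READ2,ZL111
L112.,READ2,YL112
L113.,READ2,YL113
N131.,READ2,YN131
N131.,READ2,ZN131
N132.,READ2,YN132
O141.,READ2,YO141
O141.,READ2,ZO141
O142.,READ2,YO142
O143.,READ2,YO143
P151.,READ2,YP151
P151.,READ2,ZP151
P152.,READ2,YP152
P153.,READ2,YP153
Q161.,READ2,YQ161
Q161.,READ2,ZQ161
Q162.,READ2,YQ162
Q163.,READ2,YQ163
R171.,READ2,YR171
R171.,READ2,ZR171
R173.,READ2,YR173
S181.,READ2,YS181
S181.,READ2,ZS181
S182.,READ2,YS182
S183.,READ2,YS183
T191.,READ2,YT191
T191.,READ2,ZT191
T192.,READ2,YT192
T193.,READ2,YT193
U201.,READ2,YU201
U201.,READ2,ZU201
U202.,READ2,YU202
U203.,READ2,YU203
V212.,READ2,YV212
V213.,READ2,YV213
W221.,READ2,YW221
W221.,READ2,ZW221
W222.,READ2,YW222
W223.,READ2,YW223
Y241.,READ2,YY241
Y241.,READ2,ZY241
Y242.,READ2,YY242
Y243.,READ2,YY243
Z251.,READ2,YZ251
Z251.,READ2,ZZ251
Z252.,READ2,YZ252
A261.,READ2,YA261
A261.,READ2,ZA261
A262.,READ2,YA262
A263.,READ2,YA263
B271.,READ2,YB271
B271.,READ2,ZB271
B272.,READ2,YB272
B273.,READ2,YB273
C281.,READ2,YC281
C281.,READ2,ZC281
C282.,READ2,YC282
C283.,READ2,YC283
D291.,READ2,YD291
D291.,READ2,ZD291
D293.,READ2,YD293
E301.,READ2,YE301
E301.,READ2,ZE301
E302.,READ2,YE302
E303.,READ2,YE303
F311.,READ2,YF311
F311.,READ2,ZF311
F312.,READ2,YF312
F313.,READ2,YF313
G321.,READ2,YG321
G321.,READ2,ZG321
G322.,READ2,YG322
G323.,READ2,YG323
H332.,READ2,YH332
H333.,READ2,YH333
I341.,READ2,YI341
I341.,READ2,ZI341
I342.,READ2,YI342
I343.,READ2,YI343
J351.,READ2,YJ351
J351.,READ2,ZJ351
J352.,READ2,YJ352
J353.,READ2,YJ353
K361.,READ2,YK361
K361.,READ2,ZK361
K362.,READ2,YK362
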