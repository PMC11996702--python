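muscle_code,functional_group
AT,upstroke
InS,upstroke
SuS,upstroke
AD,upstroke
LD,upstroke
TMa,upstroke
SD,upstroke
Rho,upstroke
LSD,upstroke
SubS,downstroke
SVc,downstroke
SVt,downstroke
PAnt,downstroke
PPos,downstroke
CD,downstroke
SC,downstroke
PAbd,downstroke
TB,elbow
BB,elbow
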