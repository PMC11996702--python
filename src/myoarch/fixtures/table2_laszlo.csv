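specimen_id,muscle_code,functional_group,mass_g,muscle_length_mm,fibre_length_mm,pcsa_mm2,ratio,preservation
Laszlo,AT,upstroke,0.70,29.60,23.37,28.20,0.79,fresh
Laszlo,InS,upstroke,0.25,24.52,6.06,38.89,0.25,fresh
Laszlo,SuS,upstroke,0.16,14.88,7.24,21.18,0.49,fresh
Laszlo,AD,upstroke,0.51,26.76,11.28,42.82,0.42,fresh
Laszlo,LD,upstroke,0.42,47.00,27.89,14.12,0.59,fresh
Laszlo,TMa,upstroke,0.19,25.75,14.86,12.30,0.58,fresh
Laszlo,SD,upstroke,0.26,22.00,17.67,14.04,0.80,fresh
Laszlo,Rho,upstroke,0.21,19.67,15.76,12.62,0.80,fresh
Laszlo,SubS,downstroke,0.84,34.00,14.44,55.07,0.42,fresh
Laszlo,SVc,downstroke,0.22,15.47,10.34,20.33,0.67,fresh
Laszlo,SVt,downstroke,1.14,26.00,23.11,46.50,0.89,fresh
Laszlo,PAnt,downstroke,0.15,19.35,16.27,8.73,0.84,fresh
Laszlo,PPos,downstroke,5.07,51.00,47.18,101.76,0.93,fresh
Laszlo,CD,downstroke,0.45,33.00,10.25,41.19,0.31,fresh
Laszlo,SC,downstroke,0.21,18.71,,,,fresh
Laszlo,PAbd,downstroke,0.18,45.00,41.73,4.08,0.93,fresh
Laszlo,LSD,downstroke,0.23,24.50,21.85,9.79,0.89,fresh
Laszlo,TB,elbow,1.06,36.30,10.34,97.33,0.28,fresh
Laszlo,BB,elbow,1.44,39.79,12.42,109.81,0.31,fresh
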