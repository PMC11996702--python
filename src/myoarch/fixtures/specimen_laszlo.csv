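specimen_id,species,body_mass_g,source
Laszlo,Rousettus aegyptiacus,105.0,implied jointly by published mass-normalized values
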