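(Liposcelis_bostrychophila,(Heterodoxus_macropus,((Campanulotes_bidentatus,Ibidoecus_bisignatus),(Bothriometopus_macrocnemis,(Haematomyzus_elephantis,((Haematopinus_suis,Haematopinus_apri),((Polyplax_asiatica,Polyplax_spinulosa),(Pthirus_pubis,(Pediculus_humanus_capitis,Pediculus_humanus_humanus)))))))));
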