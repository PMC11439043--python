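((Bos_taurus:0.5,Homo_sapiens:0.5):0.3,((Caenorhabditis_elegans:0.4,(Diploscapter_pachys:0.2,Diploscapter_coronatus:0.2):0.2):0.2,(Bursaphelenchus_xylophilus:0.35,(Panagrellus_redivivus:0.3,(Halicephalobus_consperatus:0.2,(Halicephalobus_mephisto:0.15,Halicephalobus_gingivalis:0.15):0.1):0.1):0.1):0.15):0.1);
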