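((('Speothos venaticus':3.2,'Chrysocyon brachyurus':3.2):1.8,('Atelocynus microtis':3.6,'Cerdocyon thous':3.6):1.4):1.0,('Lycalopex vetulus':3.4,('Lycalopex culpaeus':2.6,('Lycalopex griseus':1.5,'Lycalopex gymnocercus':1.5):1.1):0.8):2.6);
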