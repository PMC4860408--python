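species,mass_kg,diet,habitat
Atelocynus microtis,9.0,hypercarnivore,forest
Cerdocyon thous,5.2,omnivore,open
Chrysocyon brachyurus,25.0,omnivore,open
Lycalopex culpaeus,9.0,omnivore,open
Lycalopex griseus,3.3,omnivore,open
Lycalopex gymnocercus,4.7,omnivore,open
Lycalopex vetulus,3.3,insectivore,open
Speothos venaticus,5.8,hypercarnivore,forest
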