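genus	family	species_count	scheme
Diplophos	Diplophidae	7	this-study-8
Manducus	Diplophidae	2	this-study-8
Cyclothone	Gonostomatidae	14	this-study-8
Gonostoma	Gonostomatidae	2	this-study-8
Margrethia	Gonostomatidae	2	this-study-8
Sigmops	Gonostomatidae	5	this-study-8
Triplophos	Gonostomatidae	1	this-study-8
Zaphotias	Gonostomatidae	1	this-study-8
Ichthyococcus	Ichthyococcidae	7	this-study-8
Phosichthys	Phosichthyidae	1	this-study-8
Woodsia	Phosichthyidae	2	this-study-8
Araiophos	Sternoptychidae	2	this-study-8
Argyripnus	Sternoptychidae	9	this-study-8
Argyropelecus	Sternoptychidae	7	this-study-8
Danaphos	Sternoptychidae	2	this-study-8
Maurolicus	Sternoptychidae	15	this-study-8
Polyipnus	Sternoptychidae	34	this-study-8
Sonoda	Sternoptychidae	2	this-study-8
Sternoptyx	Sternoptychidae	4	this-study-8
Thorophos	Sternoptychidae	2	this-study-8
Valenciennellus	Sternoptychidae	2	this-study-8
Aristostomias	Stomiidae	6	this-study-8
Astronesthes	Stomiidae	50	this-study-8
Bathophilus	Stomiidae	20	this-study-8
Borostomias	Stomiidae	6	this-study-8
Chauliodus	Stomiidae	9	this-study-8
Chirostomias	Stomiidae	1	this-study-8
Echiostoma	Stomiidae	1	this-study-8
Eupogonesthes	Stomiidae	1	this-study-8
Eustomias	Stomiidae	134	this-study-8
Flagellostomias	Stomiidae	1	this-study-8
Grammatostomias	Stomiidae	4	this-study-8
Heterophotus	Stomiidae	1	this-study-8
Idiacanthus	Stomiidae	3	this-study-8
Leptostomias	Stomiidae	12	this-study-8
Malacosteus	Stomiidae	2	this-study-8
Melanostomias	Stomiidae	18	this-study-8
Neonesthes	Stomiidae	2	this-study-8
Odontostomias	Stomiidae	2	this-study-8
Opostomias	Stomiidae	2	this-study-8
Pachystomias	Stomiidae	1	this-study-8
Photonectes	Stomiidae	29	this-study-8
Photostomias	Stomiidae	6	this-study-8
Rhadinesthes	Stomiidae	1	this-study-8
Stomias	Stomiidae	12	this-study-8
Tactostoma	Stomiidae	1	this-study-8
Thysanactis	Stomiidae	1	this-study-8
Trigonolampa	Stomiidae	1	this-study-8
Pollichthys	Vinciguerriidae	1	this-study-8
Vinciguerria	Vinciguerriidae	5	this-study-8
Polymetme	Yarrellidae	6	this-study-8
Yarrella	Yarrellidae	2	this-study-8
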