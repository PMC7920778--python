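"""Published reference tables, transcribed verbatim, used to write fixtures.

``BEHAVIOR_COUNTS`` are the ladybird mating-trial contingency counts
(behaviour, year, species, hit, miss, false alarm, correct rejection) from
the short (2014) and long (2015) experiments.  ``SPECIES_PAIRS`` is the
24-pair comparative table of taxa exhibiting conspecific sperm precedence,
with distribution/niche categories normalised to lower-snake-case.
"""

BEHAVIOR_COUNTS = (
    ("male_mating_attempt", "2014", "H. yedoensis", 30, 115, 13, 22),
    ("male_mating_attempt", "2014", "H. axyridis", 47, 40, 10, 32),
    ("male_mating_attempt", "2015", "H. yedoensis", 28, 95, 3, 13),
    ("male_mating_attempt", "2015", "H. axyridis", 67, 26, 8, 15),
    ("female_rejection", "2014", "H. yedoensis", 16, 14, 3, 6),
    ("female_rejection", "2014", "H. axyridis", 14, 33, 7, 7),
    ("female_rejection", "2015", "H. yedoensis", 13, 18, 8, 13),
    ("female_rejection", "2015", "H. axyridis", 97, 57, 3, 0),
)

SPECIES_PAIRS = (
    ("Marine invertebrate", "Abalone", "Haliotis corrugata and H. rufescens",
     "sympatry", "Niche overlap in terms of water depth and habitat", "1-3"),
    ("Marine invertebrate", "Abalone", "Haliotis cracherodii and H. rufescens",
     "niche_partitioning", "Intertidal zone versus kelp forest habitat", "3, 4"),
    ("Marine invertebrate", "Abalone", "Haliotis fulgens and H. rufescens",
     "niche_partitioning", "Shallow versus deep water habitats", "2, 3, 5"),
    ("Marine invertebrate", "Blue mussel", "Mytilus trossulus and M. edulis",
     "sympatry", "Hybrid zone is not narrow", "6, 7"),
    ("Marine invertebrate", "Starfish", "Asterias forbesi and A. rubens",
     "sympatry", "Similar habitats, food resources, and spawning time", "8, 9"),
    ("Marine invertebrate", "Coral", "Montastraea annularis and M. franksi",
     "niche_partitioning", "Separation in (slightly overlapped) spawning time", "10"),
    ("Marine invertebrate", "Sea urchin", "Echinometra mathaei and E. oblonga",
     "sympatry", "Slight ecological differences", "11"),
    ("Marine invertebrate", "Sea urchin", "Echinometra oblonga and E. sp. C",
     "sympatry", "Slight difference in habitat but similar spawning time", "12"),
    ("Terrestrial invertebrate", "Cricket", "Allonemobius fasciatus and A. socius",
     "parapatry", "", "13, 14"),
    ("Terrestrial invertebrate", "Cricket", "Gryllus firmus and G. pennsylvanicus",
     "parapatry", "", "15, 16"),
    ("Terrestrial invertebrate", "Cricket", "Gryllus bimaculatus and G. campestris",
     "parapatry", "", "17, 18"),
    ("Terrestrial invertebrate", "Grasshopper",
     "Chorthippus p. parallelus and C. p. erythropus", "parapatry", "", "19, 20"),
    ("Terrestrial invertebrate", "Grasshopper", "Podisma pedestris races",
     "parapatry", "", "21, 22"),
    ("Terrestrial invertebrate", "Ladybird",
     "Epilachna pustulosa and E. vigintioctomaculata",
     "niche_partitioning", "Host plant separation", "23, 24"),
    ("Terrestrial invertebrate", "Ladybird", "Harmonia yedoensis and H. axyridis",
     "niche_partitioning", "Difference in prey item and habitat", "25"),
    ("Terrestrial invertebrate", "Fruit fly", "Drosophila yakuba and D. santomea",
     "parapatry", "Lowland versus highland distributions", "26, 27"),
    ("Terrestrial invertebrate", "Stalk-eyed fly",
     "Teleopsis dalmanni diverged populations", "allopatry", "", "28, 29"),
    ("Terrestrial invertebrate", "Damselfly", "Ischnura graellsii and I. elegans",
     "niche_partitioning",
     "The two species are rarely found in the same localities", "30-33"),
    ("Vertebrate", "Darter fish", "Etheostoma barrenense and E. zonale",
     "sympatry", "Not closely related within the genus", "34"),
    ("Vertebrate", "Darter fish", "Etheostoma hopkinsi and E. luteovinctum",
     "allopatry", "", "35"),
    ("Vertebrate", "Salmonid", "Salmo salar and S. trutta", "niche_partitioning",
     "Spatial and temporal segregation in spawning activities", "36-38"),
    ("Vertebrate", "Sunfish", "Lepomis macrochirus and L. gibbosus",
     "niche_partitioning", "Differences in nesting and breeding habits", "39, 40"),
    ("Vertebrate", "Bird", "Ficedula hypoleuca and F. albicollis",
     "niche_partitioning", "Separation in breeding habitat", "41-43"),
    ("Vertebrate", "Mouse", "Mus domesticus and M. musculus", "parapatry", "", "44, 45"),
)
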