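# Fixture notes

The packaged survey (`colonies.csv`, `occupancy.csv`, `taxa.csv`) is a colony-level
transcription of the published composition table of exosymbiont assemblages in
*Pocillopora damicornis* types α/β at Reunion Island (RI) and New Caledonia (NC),
joined with the published per-site colony totals. Colonies listed in no assemblage
row carry empty assemblages so that per-stratum totals match the sampling table
(234 colonies overall; analysis strata of 61, 48, 11, 56 and 40).

Abundance convention: the source table counts colonies per assemblage, not
individuals, so every occupancy row records `count = 1` (presence). Individual
counts per colony are not recoverable from the published table.

## Ambiguous composite rows and the reading chosen

Three source rows are ambiguous at the colony level; the fixture adopts one
reading and records the alternatives here rather than guessing silently:

1. *"T. septata + A. lottini L1, additional: T. serenei + A. lottini (N = 3
   juveniles)"* — one NC-LI adult α colony. Read as a single colony hosting
   {T. septata, A. lottini L1, T. serenei, A. lottini (unresolved lineage)};
   the "N = 3 juveniles" annotation refers to three juvenile shrimp
   *individuals* whose lineage was not resolved, recorded under the
   `Alot` placeholder taxon with count 1 (presence convention).
   Alternative reading: the three juveniles belong to L1 (would not change
   any key-species statistic, since L1 is already present).
2. *"T. cymodoce + A. lottini L2, additional: A. lottini L1 (N = 1 juvenile)"*
   — one NC-LI adult α colony hosting {T. cymodoce, A. lottini L2,
   A. lottini L1}; the L1 individual is a juvenile shrimp. This is the single
   colony where the two *A. lottini* lineages co-occur in NC α adults
   (published observed count: 1).
3. *"T. speciosa, additional: T. bidentata L1 + T. serenei"* — one RI-HI adult
   β colony hosting {T. speciosa, T. bidentata L1, T. serenei}. Alternative
   reading (two colonies, one with each additional crab) would break the
   RI-HI adult total of 31 and is rejected.

Column-position disambiguation: several cells of the source table cannot be
assigned to a site/stage/type column from layout alone; positions were fixed by
requiring all per-site totals and all counts printed in the study's results
(richness 37/34/12/21/31; co-occurrence 15/3/13/16/1/4; solitary 24; prose
checks 0 and 2; empty-juvenile fractions 40%/49%; occupied-juvenile counts
18/19/23/2) to hold at once. The reading shipped here satisfies every
constraint simultaneously.
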