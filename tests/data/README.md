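# Optional raw-data fixtures

The raw Cq measurements behind the published four-species study are
distributed as spreadsheet files alongside the article and are not
redistributable here, so this directory ships empty.  Tests and acceptance
targets that validate against those measurements fail with a clear message
until the data are provided in the following plain-CSV layouts:

## `stability_cq.csv`  — reference-gene stability panels

Long format, one row per technical-replicate well:

    species,tissue,sample,gene,replicate,group,cq
    piceifrons,head,iso1,Act5C,1,isolated,21.52
    ...

8 genes (Act5C, Ann, Arm, EF2, GAPDH, Hsp70, RIBL5, Tub), 4 species
(piceifrons, americana, cubense, nitens), 2 tissues (head, thorax),
5 isolated + 5 crowded samples each.  Leave the `cq` field empty for wells
removed after aberrant melt curves.

## `target_cq.csv` — target-gene quantification (piceifrons thorax)

Same columns minus `species`/`tissue`; genes are the 7 retained reference
genes plus targets `ast`, `at`, `SPPP-4`, `SPPP-5`; groups
isolated/crowded.

## `dilution_cq.csv` — primer-efficiency dilution series

    species,gene,dilution,cq
    piceifrons,Act5C,1,18.2
    piceifrons,Act5C,10,21.5
    ...

`dilution` is the fold dilution (1, 10, 100, ...), one row per replicate.
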