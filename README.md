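# amphipep

Discovery of emulsifier peptides embedded in protein sequences.

The package implements a bioinformatic pipeline for mining surface-active
peptides from proteins:

1. **seqio** — FASTA input, signal-peptide stripping (annotation-driven),
   exhaustive enumeration of 7–30-residue candidate windows, and
   single-linkage clustering of predictions at >70% sliding ungapped
   similarity.
2. **physchem** — Kyte-Doolittle hydrophobicity lookup, average molecular
   weight, Henderson–Hasselbalch net charge and isoelectric point
   (configurable pKa sets).
3. **amphiscore** — three raw amphiphilicity scores: a helical-wheel moment
   (100° per residue), a strand moment (180° per residue, the absolute
   alternating sum), and a two-block score (best hydrophobic/hydrophilic
   divide over all split positions, with the divide position reported).
4. **background** — random-peptide null models per score type and length
   (default 40,000 peptides per length, drawn from a shipped average
   Swiss-Prot residue composition) and z-normalization of raw scores, which
   removes the length bias of summed scores.
5. **structgate** — ingestion of per-residue secondary-structure probability
   profiles (generic TSV/CSV, NetSurfP-2.0-style CSV convertible), the
   0.3 average-probability gate for helical/strand candidates, and assembly
   of the ranked prediction table (threshold z > 2, clustering, Mw/pI/charge
   annotation).
6. **digestion** — rule-based protease digestion (trypsin: cleave after K/R,
   blocked by P1′ proline, slowed by acidic P1′; Asp-N supported via an
   N-terminal-side rule) and release-feasibility reports for target peptides
   (truncations, elongations, internal fast sites, verdict).
7. **abundance** — iBAQ/riBAQ computation from protein-level MS1 intensities
   (theoretical tryptic peptide counts of length 6–30 as denominator) and
   peptide-level maximum molar recovery at 100% / >90% identity tiers.
8. **fixtures** — synthetic proteins with planted amphiphilic motifs plus
   matching profiles and intensity tables, for end-to-end testing without
   any downloads.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (published masses,
divide positions, z-scores, release logic, and the property-based
substitutes for the full published hit list).

## CLI

```bash
amphipep fixtures   --out-dir fx --seed 1            # synthetic inputs
amphipep background --out bg.tsv                     # null models (n=40,000)
amphipep score      fx/proteins.fasta --out scores.tsv
amphipep predict    fx/proteins.fasta --profiles fx/profiles.tsv --out pred.tsv
amphipep digest     fx/proteins.fasta --out frags.tsv
amphipep release    fx/proteins.fasta --target synth001:10-25
amphipep abundance  fx/proteins.fasta --intensities fx/intensities.tsv \
                    --peptide LNIQFNIPTPKLC --out ab.tsv
amphipep all        --fixture-dir fx --out-dir out   # full pipeline
```

All tables are tab-delimited with `#` provenance lines; a YAML config
(`--config`) and flag overrides control the tunables (defaults: window
7–30, z > 2, gate 0.3, similarity 0.70, homolog identity > 0.90,
background n = 40,000).

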