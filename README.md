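# htt — horizontal transfer of transposable elements from sample sequences

`htt` detects horizontal transfer (HT) of transposable elements (TEs)
between diverged plant lineages using low-depth "sample sequences":
unassembled single-end shotgun reads (~151 bp, ~2.3× coverage) from
candidate donor species, compared against assembled recipient genomes. It
is aimed at researchers studying TE mobility and genome evolution in
plants (grasses especially), where assembled genomes are scarce but cheap
shallow sequencing is not.

## The idea

Between lineages that diverged long ago, vertically inherited sequence
sits near the speciation-level identity — measured by mapping sample reads
onto the recipient's coding sequences (CDS) and locating the modal
identity peak (e.g. 86%). A recently transferred element instead shows
near-identical copies in donor and recipient (>97%). The package turns
that contrast into calls and events:

* **Targeted screen** — reads carrying a reverse-transcriptase (RT) domain
  are isolated by profile scanning, clustered, and each cluster
  representative seeds a genomic window (top 3 homologies per genome,
  >85% identity over ≥140 bp, ±10 kb flanks). All reads are mapped back,
  pruned to best-nonoverlapping hits (≥100 bp matched, ≤75 bp overlap),
  and an LTR-retrotransposon is called horizontally transferred iff ≥10
  distinct reads land within the structurally annotated element at mean
  identity >97%.
* **Nontargeted screen** — reads are shredded to 50 bp and placed with ≤3
  mismatches (an exact 94% identity floor); densely mapped regions
  (>500 bp covered, gaps <150 bp) are filtered against organelle / rRNA /
  conserved-gene / low-complexity exclusion sets and re-screened with
  full-length reads at the 97% threshold.
* **Event inference** — called elements are similarity-clustered
  (single-linkage, ≥90% identity over ≥55% coverage); calls sharing a
  cluster merge into one event when a shared donor's recipients (or a
  shared recipient's donors) form one clade of the cluster tree; the
  minimum event count is one per HT cluster plus one per singleton.
  Direction comes from a phylogenetic nesting test (recipient copies
  nested in donor diversity), and UPGMA node heights on identity distances
  sketch each family's amplification history.
* **Junction verification** — TG…CA LTR termini, target-site duplications
  (TSDs), junction-spanning reads, and presence/absence of the insertion
  between conserved flanks in related genomes.

A synthetic-data generator (`htt.simulate`) builds complete scenarios with
exact ground truth — diverging genome pairs, a planted element with
LTR/TSD structure, post-transfer amplification, shredded reads — so the
entire pipeline is testable without any external data.

## Worked example

```bash
htt demo --seed 2 --genome-len 40000 --out demo/
```

runs simulation, both screens, calibration and junction checks:

```
demo: 3 targeted / 3 nontargeted call(s); calibration peak 86% -> demo/
```

`demo/targeted_calls.tsv` (three planted copies — one transfer plus two
post-transfer amplifications — all recovered):

```
donor   recipient         start  end    n_support_hits  mean_identity  mode      cluster
donor   recipient_genome   7707  12706  38              98.67          targeted  SG001
donor   recipient_genome  22231  27230  37              98.16          targeted  SG001
donor   recipient_genome  48161  53160  37              98.17          targeted  SG001
```

Each line is one called element: its interval on the recipient, the number
of distinct supporting reads (all ≥10) and their mean identity (all above
the 97% threshold, as expected for a transfer at 1.5% divergence).
`demo/calibration.json` shows why 97% is safe here: the vertical
background peaks at 86% identity and no CDS-mapped read exceeds 97%:

```json
{"peak": 86.0, "threshold": 97.0, "frac_above": 0.0, "n_hits": 114, "pass": true}
```

and the junction report for the first call confirms a genuine integration
— intact TG…CA termini and a 5-bp target-site duplication:

```json
{"ltr5_motif_ok": true, "ltr3_motif_ok": true, "tsd_seq": "CTCCT"}
```

The same stages are available as library functions (`htt.pipeline`,
`htt.htscan`, `htt.phylo`, `htt.junctions`) and as individual subcommands
(`htt simulate|align|calibrate|scan-targeted|scan-nontargeted|cluster|
events|history|junctions`). Every output file gets a JSON provenance
sidecar recording the tool version, seed and thresholds.

## Documentation

`docs/methods.md` describes the detection model, the alignment engines and
their statistics, the identity semantics (full-read-span identity for
divergence estimation vs HSP identity for the published hit rules), the
profile scanning and its calibrated thresholds, the event-merge and
nesting formalizations, what the simulator does and does not emulate, and
the package's numerical conventions.
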