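# difmod

Detection and analysis of Xer/dif recombination sites and the mobile **dif
modules** they delimit on bacterial replicons, with *Acinetobacter* plasmids
and chromosomes as the motivating system.

## The problem

Bacterial chromosomes carry a single 28-bp *dif* site near the replication
terminus where the XerC/XerD tyrosine recombinases resolve chromosome
dimers. *Acinetobacter* plasmids, unusually, often carry many dif-like sites
(**pdif** sites), and pairs of adjacent sites can bracket adaptive cargo
genes — tellurium or organic-peroxide resistance, sulfate and potassium
transporters, toxin–antitoxin pairs — forming **dif modules**, a class of
Xer-dependent mobile genetic elements. `difmod` is a reusable, tested
pipeline for the comparative-genomics workflow around these elements:

1. **Site scanning** — every forward-strand 28-bp window of a replicon is
   scored against a reference site pair by ungapped identity
   (matches/28). A site is reported when identity ≥ a threshold (default
   0.75). Orientation is called **CD** (XerC-arm/XerD-arm order on the
   forward strand) or **DC** for the reverse arrangement; each site
   decomposes as 11-bp XerC arm + 6-bp central region + 11-bp XerD arm.
2. **Module calling** — consecutive site pairs whose inclusive span
   (both flanking sites counted) is ≤ 20 kb and that contain a cargo ORF
   ≥ 150 bp become candidate modules; cargo is labelled against a catalog
   by infix alignment identity ≥ 0.90.
3. **Mobility assessment** — near-identical module copies (global
   alignment identity ≥ 0.98) lying in different sequence contexts
   (500-bp flank identity < 0.80) on different replicons are evidence of
   horizontal transfer. Families are grouped by single linkage at 0.95.
4. **Site clustering and consensus profiling** — blastclust-style
   single-linkage clustering at 0.95 identity (at 28 bp: at most one
   mismatch per link), per-position base frequencies, information content
   `IC(p) = 2 − H(p)` bits, and Jensen–Shannon divergence between site
   groups (e.g. plasmid pdif vs chromosomal dif1 vs additional chromosomal
   sites).
5. **Synthetic data** — a generator that plants sites and modules at
   controlled divergence into site-free random replicons and emits full
   ground truth, so every stage is testable without downloads.

The packaged reference sites and cargo catalog are **synthetic stand-ins**
(files named `synthetic_*`): they reproduce the architecture and the
published lengths of the real elements, not their database sequences, and
can be replaced with real references via `--refs` / `--catalog`.

## Worked example

Simulate a small plasmid collection, then run the full pipeline:

```bash
difmod simulate --spec spec.yaml --out-dir sim --seed 42
# spec.yaml: n_replicons: 12, n_transfer_events: 1, n_single_modules: 1
difmod scan --fasta sim/replicons.fasta --out sites.tsv --bed sites.bed
difmod modules --fasta sim/replicons.fasta --sites sites.tsv --out modules.gff3
difmod mobility --fasta sim/replicons.fasta --modules modules.gff3 --out mobility.json
difmod cluster --sites sites.tsv --fasta-out clustered.fa
```

Scan output (per replicon: length, CD and DC site counts):

```
synthetic_replicon_003	214123 bp	CD=4	DC=0
synthetic_replicon_004	39265 bp	CD=1	DC=1
synthetic_replicon_010	232060 bp	CD=6	DC=4
...
```

Module calls (span is inclusive of both 28-bp flanking sites — a module
whose flanks sit at 37080–37107 and 40063–40090 has length 3011):

```
synthetic_replicon_004	37080-40090	3011 bp	chrA-chrB_dif
synthetic_replicon_008	201842-204390	2549 bp	kup-orfY_dif
synthetic_replicon_010	89509-92057	2549 bp	kup-orfY_dif
```

Mobility: the module planted onto two replicons in fresh contexts is called
mobile; the single-copy module is not:

```
kup-orfY_dif	occurrences=2	mobile=True
chrA-chrB_dif	occurrences=1	mobile=False
```

Clustering groups the 22 detected sites by ≥ 95% identity (clusters sorted
by size, members consecutive in the FASTA output):

```
cluster 1: 13 sites (representative synthetic_replicon_003:13683)
cluster 2: 5 sites (representative synthetic_replicon_004:798)
...
```

The same operations are available as a library
(`difmod.scan_replicon`, `difmod.call_and_label_modules`,
`difmod.assess_all`, `difmod.cluster_sites`, `difmod.build_profile`,
`difmod.generate_dataset`, ...).

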