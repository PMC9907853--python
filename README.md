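# aimdock

Discovery of ATG8-interaction motifs (AIM, also called LC3-interacting
regions, LIR) guided by predicted complex structures.

## The problem

Selective autophagy is wired through short linear motifs: cargo
receptors, adaptors and even pathogen virulence factors dock onto
ATG8/LC3/GABARAP-family proteins through the AIM/LIR motif, whose
canonical consensus is

```
[W/Y/F] - X - X - [L/I/V]
```

an aromatic anchor, two spacer residues, and a hydrophobic anchor.  The
two anchors insert into two conserved hydrophobic pockets on the ATG8
ubiquitin-like fold — the W-site (site 1) and the L-site (site 2) — and
acidic residues flanking the core strengthen docking against the basic
rim of the pockets.  The consensus is so permissive that a naive scan of
a single protein typically yields many candidate windows, nearly all of
them non-functional, and noncanonical motifs (anchors or spacings that
violate the consensus, such as ILVV, MLVV, YDFM, WxxT or the
five-residue WDVSV) match no sequence pattern at all.

Structure predictors such as AlphaFold2-multimer change the game:
predicted receptor–candidate complexes show directly which residues sit
in which pocket.  `aimdock` implements everything around the predictor
that turns its output into motif calls:

* **seqmotif** — consensus scanning (all overlapping windows, 1-based
  coordinates), flank acidity, alanine masking of the two anchor
  positions (WEVV → AEVA), core truncation, and window swapping for
  positional-preference experiments;
* **pocket_atlas** — operational W/L-pocket definitions from a bound
  reference complex (5.0 Å heavy-atom rule) and alignment transfer of
  pocket positions onto any ATG8-family homolog;
* **complex_interface** — PDB/mmCIF parsing with pLDDT from B-factors
  or ColabFold scores JSON, inter-chain contact maps (4.5 Å heavy-atom
  cutoff), pocket-occupancy calling, canonical / extended-canonical /
  noncanonical verdict classification, interface confidence (mean pLDDT
  over the docked core), model re-ranking by interface confidence, Kabsch
  Cα superposition, and a disorder-context proxy from monomer pLDDT;
* **conservation** — anchor-class retention of a motif across a homolog
  MSA, with gap-aware eligibility;
* **fixtures** — synthetic planted-truth complexes, ranked model series,
  MSAs and surrogate sequences that make the whole pipeline testable
  offline;
* **workflow** (`aimdock` CLI) — the iterative discovery loop: scan,
  analyse supplied models, call the headline verdict, emit masked
  sequences for the next prediction round, and write JSON/TSV reports.

The predictor itself is an explicit external step: `aimdock` consumes
its ranked model files and produces its next input FASTA, and never runs
inference.

## Worked example

Generate a synthetic docked complex with a planted WEEL motif and
analyse it:

```bash
aimdock fixtures --preset docked --seed 0 --out demo/
aimdock pockets --complex demo/fixture_seed0_unrelaxed_rank_001.pdb \
    --receptor A --peptide B --aromatic 5 --hydrophobic 8 \
    --out demo/pockets.json
aimdock analyze --models demo/ --pockets demo/pockets.json \
    --out demo/verdicts.json
```

which prints

```
{"pockets": "demo/pockets.json", "composition": {"w_site": {"F": 1, "L": 1, "V": 1}, "l_site": {"I": 1, "Y": 1, "P": 1}}}
1/1 docked -> demo/verdicts.json
```

`demo/verdicts.json` then contains the motif call for the model:

```json
{
  "docked": true,
  "w_occupant": {"chain": "B", "position": 5, "aa": "W", "n_contacts": 3, "min_distance_A": 2.421},
  "l_occupant": {"chain": "B", "position": 8, "aa": "L", "n_contacts": 3, "min_distance_A": 2.421},
  "separation": 3,
  "motif_class": "canonical",
  "core_sequence": "WEEL",
  "interface_plddt": 90.0,
  "confidence_bin": "high"
}
```

The tryptophan at peptide position 5 occupies the W-site and the
leucine at position 8 the L-site, three residues downstream — a
canonical motif — and the mean pLDDT over the docked core (90.0) falls
in the "high" confidence bin.  On real ColabFold output the same
commands apply, pointed at a directory of ranked models; `aimdock run`
wraps scan + analyse + report + mask emission into one discovery round.

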