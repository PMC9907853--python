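# Methods

## Motif model

The canonical AIM/LIR consensus is modelled as an ordered list of
position classes: `[{W,Y,F}, ANY, ANY, {L,I,V}]`, where `ANY` is the
full 20-letter standard alphabet.  Nonstandard codes (X, U, B, Z) are
legal in sequences but satisfy no position class, including the spacer
class: an ambiguous residue cannot be claimed to match.  Scanning
reports **every** window that satisfies the classes, overlapping windows
included, because candidate totals in this field are naive window
counts; collapsing overlaps would make counts incomparable across tools.
Coordinates are 1-based inclusive everywhere, matching the
`(172)WxxL(175)` convention used to report motif loci.

Flank acidity counts only D and E in a 4-residue window on either side
of the core (truncated at sequence ends).  Phospho-mimicking S/T
residues also acidify flanks in vivo, but post-translational
modification is outside what a structure predictor sees, so it is
deliberately not modelled.

In-silico masking follows the validated mutant design: alanine
substitution touches only the two anchor positions (WEVV → AEVA),
preserving length and register, while truncation deletes the whole core.
Window swapping exchanges core ± 4-residue flanks and is an involution
on equal-length windows; it exists to probe a predictor's N-terminal
positional preference.

## Pockets

The W-site and L-site are defined operationally rather than copied from
any published residue list: given a reference complex with a bound
peptide, a receptor residue joins a site when any heavy atom lies within
5.0 Å of any heavy atom of the corresponding anchor residue.  5.0 Å is
a standard first-shell contact distance; it is a parameter, not a claim.
Definitions transfer to homologs through global Needleman–Wunsch
alignment (BLOSUM62, gap open 10, extend 0.5 — ATG8-family proteins are
short and globally alignable) with positions aligned to gaps dropped and
reported, and a 30% identity floor below which transfer is refused.
Pocket positions keep the numbering of the structure or sequence they
were defined on so that verdicts remain citable against the file.

The bundled `data/reference_pockets.json` is derived from the package's
own synthetic reference complex and exists so the CLI works out of the
box; real analyses should derive pockets from a real receptor–peptide
structure with `aimdock pockets`.

## Docking verdicts

Contacts use a 4.5 Å heavy-atom cutoff, the common protein-interface
convention; both cutoffs are configurable.  The occupant of a pocket is
the candidate residue with the most heavy-atom contact pairs to the
pocket residues, with ties broken by smaller minimum distance, then by
lower residue position — visual inspection picks occupants by eye, and a
deterministic rule is required to replace it.

A verdict is *docked* when both pockets are occupied by residues of one
candidate chain with the L-site occupant 2–6 positions downstream of the
W-site occupant.  The bounds admit the canonical separation (3) and the
extended five-residue register (4) seen in shuffled motifs while
rejecting absurd geometries.  Classification: canonical when the anchors
are W/Y/F and L/I/V at separation 3; extended-canonical when the anchor
classes hold at another legal separation; noncanonical otherwise, which
covers the known ILVV, MLVV, YDFM and WxxT cores.  A verdict is always
reported; a separate `confident_call` flag requires mean core pLDDT
above 70, because high confidence without docking and docking at low
confidence both occur — confidence is necessary, not sufficient.

Interface confidence is the arithmetic mean of pLDDT over the docked
core on the candidate chain.  pLDDT bins use half-open intervals
(90, 100] very_high, (70, 90] high, (50, 70] low, [0, 50] very_low; the
common verbal convention leaves the boundary values ambiguous, so the
boundaries 50, 70 and 90 are assigned to the lower bin and that choice
is stated here and in the output.

Model ranking orders docked models by interface pLDDT (descending, ties
by original predictor rank), then undocked models in original order.
The headline verdict is always the first entry of this ranking, never
blindly the predictor's global rank-1: a global score can be dominated
by well-predicted regions far from the interface while a lower-ranked
model docks the motif confidently.

pLDDT sourcing: a ColabFold scores JSON, when present, overrides the
B-factor column (the JSON is written with more precision and is
authoritative); disagreements are logged.  Model rank is parsed from
`rank_N` file naming, defaulting to 1.

Superposition is closed-form Kabsch least squares over mapped Cα atoms
(SVD with a determinant correction against reflections), requiring at
least 3 pairs.  Disorder context is proxied from single-chain pLDDT:
all core residues below 50 → disordered, all at or above 70 → ordered,
otherwise partially disordered.  This is a confidence-based proxy, not a
trained disorder predictor, and is labelled as such in reports.

## Conservation

Retention across a homolog MSA tests only the two anchor columns against
their position classes; spacers are unconstrained in the consensus and
never affect the call.  A strict-identity mode (exact core match) is
available behind a flag.  Rows with a gap at an anchor column are
removed from the denominator and flagged separately: an unalignable
region is absence of evidence, not evidence of loss.  The tool reports
fractions and per-species calls; it sets no threshold for declaring a
motif "conserved" — that judgement stays with the user.  Homolog
retrieval and alignment construction (BLAST, Clustal Omega, MAFFT) are
upstream of this package, which consumes a prepared MSA.

## Synthetic fixtures and what they do (not) show

The complex generator builds a receptor as a straight Cα/Cβ scaffold
(3.8 Å spacing) with two three-residue pocket cages, and a peptide
backbone 6.5 Å above it; only the two planted anchor residues extend a
side-chain pseudo-atom down to 3.0 Å above the cage centre, giving each
anchor exactly three heavy-atom contacts with its own pocket and no
other inter-chain contacts.  All engineered distances sit at least
0.3 Å away from the 4.5/5.0 Å cutoffs so that floating-point error under
rigid transformations can never flip a contact.  Decoys rigidly
translate the peptide 10–40 Å away.  Coordinates are generated on a
0.001 Å grid and pLDDT on a 0.01 grid so files round-trip exactly
through the PDB writer.  Everything is reproducible from the
`FixtureSpec` seed, byte for byte.

These fixtures are geometric idealizations.  They exercise every
deterministic computation in the package — contact detection, occupancy
ranking, verdict classification, confidence aggregation, ranking,
superposition, report plumbing — and none of the failure modes of real
predictions (compressed interfaces, partial docking, correlated pLDDT
error).  Passing the fixture battery therefore demonstrates that the
machinery is correct, not that any particular real protein docks.

The sequence surrogates (`*_surrogate`) plant documented motif loci and
window counts into backgrounds drawn from an alphabet with no aromatic
and no hydrophobic-anchor residues, so the planted windows are provably
the only consensus matches.  They stand in for validation-set sequences
that cannot be redistributed with the package; counts measured on them
validate window counting and coordinate bookkeeping only.  The
36-sequence battery plants 310 canonical windows in total, with the
named members carrying their documented per-protein counts and loci.

The synthetic MSA generator controls retention per row by either keeping
the core verbatim or substituting the aromatic anchor with serine;
background columns come from the neutral alphabet.  It does not emulate
realistic substitution processes or indel structure.

## Workflow conventions

A discovery round scans each candidate, analyses whatever models are
present in the models directory (matched by filename prefix), and
reports a candidate with no models as `awaiting prediction` — the loop's
normal intermediate state, not an error.  Masked loci accumulate across
rounds.  The default masking strategy is alanine substitution because it
preserves register and length; truncation is available.  The loop stops
when a round yields no docked verdict; this stopping rule is a
convention of this tool.  Reports are JSON (validated against the
shipped schema, carrying a hash of the pocket definition and per-model
provenance) plus a flat TSV.  Round configuration comes from a YAML file
with CLI flags overriding it.

Verdict-to-sequence mapping assumes the candidate chain numbering in the
model equals the 1-based positions of the submitted sequence, which
holds for predictor output on full sequences; when masking has shifted
the register the mapping refuses rather than guesses.

## Problem sizes

The default verification battery uses 1,000 random sequences for the
scanner oracle, 100 random two-chain geometries (20 residues × 2 atoms
per chain) for the contact oracle, 100 random rigid transforms, 200
docked fixtures and 200 displaced decoys, and a one-candidate discovery
round run twice for byte-level determinism.  These sizes give exact
(100% / 0%) expectations on every check while the whole battery runs in
seconds on one CPU.

## Known limitations

* No binding-affinity estimate of any kind; a docked verdict is a
  geometric statement about a predicted model.
* No modelling of post-translational modifications, conditional binding
  or partner-dependent docking; motifs whose ATG8 engagement depends on
  such context will be missed by any pipeline built on unmodified
  sequences.
* Non-pocket interfaces are reported only as "not docked" plus the raw
  contact map; the package does not interpret alternative binding modes.
* The disorder call is a pLDDT proxy, not a disorder predictor.
* The bundled pocket definition is synthetic; real analyses must derive
  pockets from a real reference complex.
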