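# turnprint

Structural analysis toolkit for deciding whether a protein aggregate
presents a conformation-specific turn epitope. It provides:

- **structure I/O** — a lightweight PDB reader/writer with a uniform
  structure/trajectory data model (multi-model PDB files are treated as
  trajectories with a fixed topology);
- **geometry** — Cα turn-span measurement and sharp/wide/extended
  classification, Kabsch superposition, per-frame LRMSD, per-residue RMSF,
  and Shrake–Rupley solvent-accessible surface area;
- **interaction fingerprints** — detection of hydrogen bonds (3.5 Å),
  hydrophobic contacts (5 Å), ionic interactions (6 Å), aromatic–aromatic
  pairs (4.5–7 Å), aromatic–sulphur contacts (4.3 Å) and cation–π
  interactions (6 Å) across a two-sided interface, with residue pairs that
  carry both a hydrogen bond and an ionic interaction labeled salt bridges;
- **occupancy** — the fraction of trajectory frames in which each contact
  exists, with high/low labeling;
- **an epitope classifier** — a per-chain conjunction of *sharp turn* +
  *solvent-exposed key lysine* + *no sequestering salt bridge* +
  *uncrowded turn*, aggregated into a positive/negative verdict;
- **synthetic generators** — seeded, byte-deterministic fixtures: turn
  peptides with target spans, interfaces with planted contacts,
  trajectories with planted occupancy, and multimer stacks with controlled
  spacing.

## CLI

The `turnprint` command (also `python -m turnprint.cli`) has five
subcommands:

```sh
# per-chain turn span/class and key-residue exposure
turnprint profile structure.pdb

# interaction records across an interface (chain sets on each side)
turnprint fingerprint complex.pdb --split HL:AB --frames last

# per-contact occupancy over a multi-model trajectory
turnprint occupancy trajectory.pdb --split A:B --window -10:

# aggregate positive/negative verdict with a per-chain criteria trace
turnprint classify aggregate.pdb --epitope 25:29 --key 28 --report out.json

# synthetic fixtures
turnprint synth turn_peptide --span 6.6 --seed 1 --out turn.pdb
turnprint synth contact_interface --contacts salt_bridge:2.9,hbond:3.0 --out iface.pdb
```

All thresholds (turn-class boundaries, SASA exposure threshold, clearance
radius, interaction cutoffs, occupancy threshold, epitope window) live in
a JSON config (`--config`); every report embeds the effective config.

## Deposited entries

Comparisons against deposited structures read plain-text PDB files from
`data/pdb/`. Populate the cache once, where a network is available:

```sh
turnprint fetch 5hoy 3moq 2lmn 2lmo 5aef 2beg 2mxu
```

Core analysis commands never touch the network.

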