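# sprmap

Operator-site mapping by surface plasmon resonance (SPR) with reusable
indirect DNA capture. The toolkit covers the full workflow for locating and
characterising protein binding sites on DNA without nuclease footprinting:

* **seqdesign** — oligomer panel design: overlapping tiling fragments that
  guarantee any site up to a chosen length is fully contained in at least one
  fragment; serial 2-nt truncation series for boundary mapping (including the
  duplex inversion needed to truncate the left-hand end away from the capture
  linker); single-base substitution panels with wild-type controls; DNA and
  protein molecular-weight utilities; a chip-budget calculator.
* **sensorgram** — cycle representation with named phase windows, double
  referencing, report-point extraction (+10 s after injection end for
  screening, −4 s before for affinity), theoretical-Rmax computation
  (mass-ratio × captured response × stoichiometry), %Rmax normalisation and
  dissociation/salt-wash retention summaries.
* **binding** — 1:1 Langmuir kinetics for simulation and steady-state
  affinity fitting (`R = Rmax·C/(K_D + C)`) with standard errors.
* **footprint** — screening hit calling (≈100% of theoretical Rmax at the
  top concentration), merging of adjacent hits into a starting oligomer, and
  boundary calling from truncation metrics at the truncation-step resolution.
* **motif** — degenerate consensus derivation from aligned footprints,
  palindrome symmetry annotation, IUPAC motif scanning of genomes on both
  strands, and nearest-downstream-feature context reporting (BED/GFF3).
* **fixtures** — seeded synthetic experiments (screening, truncation,
  affinity) with known ground truth; byte-reproducible from their seed.

## CLI

All commands are subcommands of `sprmap`:

```bash
# tile a region into capture-ready fragments
sprmap design-tiles --fasta region.fa --fragment-length 29 --site-length 22

# serial truncations for one boundary
sprmap design-truncations --start-fasta start.fa --side RH --step 2 --max-delta 12

# substitution panel over conserved positions
sprmap design-substitutions --start-fasta start.fa --positions 6,7,9,10,14,15,16,17

# report points, %Rmax and retention for every cycle
sprmap normalize --sensorgrams s.csv --phases p.yaml --mode screening \
    --mw-analyte 41046 --panel panel.tsv

# steady-state K_D fit (CSV columns: conc_nM, response_ru)
sprmap fit-kd --points points.csv

# synthetic kinetic cycle
sprmap simulate --params params.yaml --seed 7 --out sim.csv

# hit calling and footprint assembly
sprmap call-hits --screening screen.tsv --top-conc 100
sprmap call-footprint --metrics rh.tsv lh.tsv --start-fasta start.fa

# consensus and genome scanning
sprmap consensus --seqs fp1.fa --seqs fp2.fa
sprmap scan --genome genome.fa --motif TTnAAnnnTCAA --features genes.gff3

# complete synthetic experiment set with ground truth
sprmap make-fixtures --preset paper-like --seed 42 --out fixtures/
```

Sensorgram CSV dialect: header `cycle,flow_cell,time_s,response_ru`; phase
windows travel in a JSON/YAML sidecar `{cycle_id: {phase: [t0, t1]}}`.
Panel TSVs have the columns
`name, forward_5to3, reverse_5to3, overhang_host, region_start, region_end, delta, side`.

## Conventions

* Coordinates are 1-based and inclusive on the forward strand; RH/LH
  boundaries are defined relative to the forward strand.
* DNA strand masses use average nucleoside masses with 5′-OH termini plus
  one bridging phosphate per internal linkage; protein masses are average
  residue masses plus one water.
* Concentrations are molar internally; CLIs accept nanomolar.
* All randomness flows through explicit integer seeds.
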