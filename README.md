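# acidstab

Quantitative tools for judging concentrated sulfuric acid (CSA) as a solvent
for complex chemistry. The package predicts half-lives of organic molecules
in CSA from functional-group kinetics, derives cloud-droplet acid
concentrations from temperature and humidity profiles, computes dataset-level
stability and chemical-diversity statistics, and exhaustively enumerates all
molecules buildable from an atom palette.

## How it works

1. **Parse** molecules from SMILES (`acidstab.chem_io`); salts are reduced to
   their largest covalent component, invalid input is logged, never fatal.
2. **Match** reactive functional groups by SMARTS with precedence resolution
   (`acidstab.fg_registry`): compound groups such as the 1,2-diol outrank
   their constituents, and copy counts are symmetry-deduplicated.
3. **Rate lookup** (`acidstab.kinetics`): ln k grids over acid wt% x kelvin,
   interpolated bilinearly in (wt%, 1/T), clamped with a flag outside the
   grid. Half-lives: `t = ln 2 / k`, corrected for N copies of a group via
   `t = -ln(1 - 0.5^N) / k`. A molecule decays at the rate of its fastest
   group.
4. **Atmosphere** (`acidstab.atmosphere`): droplet acid concentration from
   water partial pressure and temperature, assuming vapor equilibrium;
   altitude profiles with consistent interpolation.
5. **Stability & summaries** (`acidstab.stability`): per-(molecule, altitude)
   half-lives, stability bands (`<1 s` ... `>1e8 s`), stable fractions above
   a reference altitude, geometric-mean half-lives, band histograms.
6. **Diversity** (`acidstab.diversity`): bond-type counts of stable subsets
   and per-element stability fractions, size-weighted across datasets.
7. **Enumeration** (`acidstab.enumerate`): every connected neutral structure
   from a palette (e.g. C,N,O,Si + implicit H) within a heavy-atom size
   range and a minimum ring size, deduplicated exactly via automorphism-orbit
   representatives, with an independent brute-force oracle for small specs.
8. **Synthetic fixtures** (`acidstab.synthdata`): seeded rate grids, molecule
   sets with planted group content, and model atmospheres with known ground
   truth, so the full pipeline is testable offline.

Predictions are order-of-magnitude by design; compare log10 values, not
digits. The shipped functional-group registry is an illustrative ~20-group
set with placeholder kinetics — real measured rate tables can be supplied as
CSV (`group_id,acid_wt_pct,temperature_K,ln_k,provenance`).

## CLI

```sh
acidstab load --in mols.smi --format smiles --dedup --out clean.csv
acidstab match --in clean.csv --out matches.csv
acidstab synth rates --seed 1 --out rates.csv
acidstab synth atmosphere --seed 1 --out profile.csv
acidstab synth molecules --seed 1 --n 100 --out mols.csv
acidstab profile --in levels.csv --out levels_acid.csv
acidstab rate --rates rates.csv --group amine --at 85,280
acidstab stability --molecules mols.csv --rates rates.csv \
    --profile profile.csv --out results.csv --summary summary.csv
acidstab diversity --molecules mols.csv --results results.csv \
    --thresholds 1,1e3,1e6 --out diversity.csv
acidstab enumerate --palette C,N,O,Si --sizes 3:8 --min-ring 5 --count
```

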