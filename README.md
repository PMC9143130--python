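# pmfkit

Umbrella sampling → WHAM → spline-corrected free-energy profiles, plus the
structural descriptors used to interpret covalent enzyme inhibition.

## Who this is for

Computational chemists and structural bioinformaticians who characterise a
covalent inhibition (or any activated process driven by a scalar reaction
coordinate) with biased molecular simulations: scan a surface, place
harmonic umbrella windows, recombine the biased histograms into a potential
of mean force W(ξ), correct a cheap-Hamiltonian surface toward a high-level
one, trace the reaction path across a 2D surface, and assemble labeled
stationary points into a free-energy profile from which forward and reverse
barriers can be queried.  A synthetic-data module (analytic surfaces with
known barriers, molecular fixtures with prescribed geometry) stands in for
the QM/MM engine, so the whole pipeline is testable on a laptop.

## The core quantities

The PMF along a coordinate ξ is

    W(ξ) = C − kT · ln ⟨δ(ξ(r) − ξ)⟩,

estimated from umbrella windows (harmonic biases ½k(ξ−ξ₀)², default
k = 2500 kJ·mol⁻¹·Å⁻² = 597.51 kcal·mol⁻¹·Å⁻², T = 310 K) by the weighted
histogram analysis method, iterated to a density tolerance of 10⁻³.  The
activation free energy is read from the profile as
ΔG‡ ≈ W(ξ‡) − W(ξ_R) = ΔW‡.  Dual-level correction adds an interpolated
high-level-minus-low-level difference, E = E_LL + S[ΔE_LL→HL](ξ₁, ξ₂).  On
2D surfaces a maximum-probability path is traced and its 1D profile
obtained by integrating exp(−W/kT) perpendicular to the path.  The
descriptor suite measures the Bürgi–Dunitz (α_BD) and Flippin–Lodge (α_FL)
nucleophilic-attack angles, geometric hydrogen bonds (≤ 3.0 Å, ≥ 135°),
Kabsch-superposed RMSD, ring-puckering torsions, Eisenberg hydrophobicity,
and per-residue E_int = E_elec + E_vdW with a smooth 14.5–16 Å switch.

## Worked example

Recover a known 5 kcal·mol⁻¹ barrier from umbrella sampling, then correct
it to a high-level surface with an 8 kcal·mol⁻¹ barrier:

```python
import numpy as np
import pmfkit as pk

ll = pk.make_double_well(5.0, 1.0)        # V(x) = 5((x/1)^2 - 1)^2
hl = pk.make_double_well(8.0, 1.0)
pair = pk.make_llhl_pair(ll, hl)

grid = pk.grid_scan(ll, [(-1.5, 1.5, 0.1)])          # 31 nodes
plan = pk.build_windows(grid)                        # k = 597.51, T = 310 K
windows = pk.sample_windows(ll, plan, seed=0)        # 20 000 samples/window
pmf = pk.wham(windows)                               # tolerance 1e-3

i0 = np.argmin(np.abs(pmf.axes[0]))
print(f"LL barrier: {pmf.values[i0] - np.nanmin(pmf.values):.2f} kcal/mol")

nodes = np.arange(-2.0, 2.01, 0.2)
corr = pk.build_correction(nodes, pair.delta(nodes))
fixed = pk.apply_correction(pmf, corr)
print(f"corrected barrier: {fixed.values[i0] - np.nanmin(fixed.values):.2f} kcal/mol")
```

Output:

```
LL barrier: 5.21 kcal/mol
corrected barrier: 8.21 kcal/mol
```

The low-level estimate lands within the ±0.3 kcal·mol⁻¹ statistical budget
of the analytic barrier, and the spline correction carries the profile to
the high-level answer without re-sampling.

Profiles assembled from labeled stationary points answer barrier queries in
both directions — for example, a profile whose rate-limiting saddle sits at
24.9 kcal·mol⁻¹ and whose product complex sits at −15.6 kcal·mol⁻¹ gives a
reverse barrier of 40.5 kcal·mol⁻¹, the arithmetic behind calling a
covalent adduct irreversible:

```python
profile = pk.assemble_profile([
    [("E•I", 0.0), ("TS1", 24.9), ("E-I2", 1.9)],
    [("E-I2", 1.9), ("TS3", 21.0), ("E-PC", -15.6)],
])
pk.barrier_query(profile, "E-PC", "E•I")   # 40.5
```

A `pmfkit` command-line tool exposes the same pipeline as composable
stages (`make-toy`, `scan`, `sample`, `wham`, `correct`, `path`,
`profile`, `geometry`, `interactions`); logs go to stderr, results to
files, and fixed seeds make every stage byte-reproducible.

## Layout

- `src/pmfkit/toys.py` — analytic surfaces, LL/HL pairs, molecular fixtures
- `src/pmfkit/coords.py` — distance / antisymmetric / dihedral coordinates
- `src/pmfkit/sampling.py` — BAOAB Langevin sampler, grid scans, windows
- `src/pmfkit/wham.py` — WHAM estimator, barriers, path tracing, profiles
- `src/pmfkit/dual_level.py` — spline correction (`SplineCorrection`)
- `src/pmfkit/geometry.py` — attack angles, H-bonds, RMSD, puckering
- `src/pmfkit/interactions.py` — per-residue nonbonded decomposition
- `src/pmfkit/io.py`, `src/pmfkit/cli.py` — PDB/XYZ/TSV/YAML formats, CLI

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
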