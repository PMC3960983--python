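# amdkit

A desk-scale toolkit for **accelerated molecular dynamics (aMD)** enhanced
sampling and **free-energy-landscape analysis**, built around the reaction
coordinates used to characterise G-protein-coupled-receptor (GPCR)
activation — the Arg^3.50–Glu^6.30 ionic lock, the Trp^6.48 toggle-switch
side-chain dihedrals (χ1, χ2), and the Tyr^5.58–Tyr^7.53 hydroxyl pair of
the M2 muscarinic receptor.

It is aimed at people who want to understand, prototype or test aMD
analysis pipelines — boost mathematics, potential-of-mean-force (PMF)
estimation, bin-size precision checks and energetic reweighting — on
analytic toy systems and synthetic data, without a supercomputer or a
membrane-embedded receptor simulation.

## The method

aMD adds a non-negative boost potential when the system potential V(r)
falls below a reference energy E:

    V*(r) = V(r)                          V(r) ≥ E
    V*(r) = V(r) + ΔV(r)                  V(r) < E
    ΔV(r) = (E − V(r))² / (α + E − V(r))

The acceleration factor α controls the flattening: smaller α flattens more,
α → ∞ recovers conventional MD.  Forces on the modified surface are the
unbiased forces scaled by dV*/dV = α²/(α + E − V)² ∈ (0, 1], so barriers
shrink while the ordering of states is preserved.  In **dual-boost** aMD a
dihedral-term boost is applied first and a total-energy boost on top; for
membrane-protein systems the parameters follow the standard recipe from
short conventional-MD averages,

    E_dihed = V_dihed_avg + λ·V_dihed_avg     α_dihed = λ·V_dihed_avg / 5
    E_total = V_total_avg + 0.2·N_atoms       α_total = 0.2·N_atoms

with λ = 0.3 the recommended acceleration.

A PMF over a reaction coordinate ξ is estimated as F_i = −k_BT·ln P_i from
the binned frame distribution (minimum shifted to zero), with a
multi-bin-size sweep (0.1–0.5 Å for distances, 3–15° for dihedrals, 6° for
2D dihedral maps) as the precision check: converged sampling gives
near-identical profiles at every bin size.  Canonical statistics are
recovered from boosted frames either exactly, by weighting each frame with
the Boltzmann factor of its boost e^{ΔV/k_BT}, or approximately by a
cumulant expansion per bin, F_i → F_i − [⟨ΔV⟩_i + (β/2)·Var(ΔV)_i], which
is exact for Gaussian ΔV and much less noisy when the boost distribution is
broad.

## Worked example

```python
import amdkit as ak
from amdkit.free_energy import pmf_1d, reweight_series, bin_size_sweep, find_minima

state = ak.ThermodynamicState(temperature=300.0)  # k_B T = 0.596 kcal/mol

# an aMD-boosted Langevin run on a 2 kcal/mol double well
well = ak.make_double_well(barrier_height=2.0, well_separation=1.0)
boost = ak.BoostSpec(reference_energy=2.5, acceleration_factor=2.5)
cfg = ak.SimulationConfig(n_steps=1_000_000, save_stride=100, rng_seed=1,
                          initial_position=-1.0, boost=boost)
traj = ak.langevin_simulate(well, cfg)
series = ak.RCSeries(traj.coordinate(), unit="reduced", delta_v=traj.delta_v)

boosted = pmf_1d(series, 0.1, state)
recovered = reweight_series(series, 0.1, state, "exponential")
exact = ak.analytic_pmf(well, state, boosted.bin_edges)

def barrier(p):
    return float(p.value_at(0.0) - min(p.value_at(-1.0), p.value_at(1.0)))

print(f"true barrier        : {barrier(exact):.2f} kcal/mol")
print(f"boosted (apparent)  : {barrier(boosted):.2f} kcal/mol")
print(f"after reweighting   : {barrier(recovered):.2f} kcal/mol")

# the synthetic ionic-lock landscape and its bin-size precision check
il = ak.synth_rc_series(n_frames=100_000, rng_seed=1)
report = bin_size_sweep(il, (0.1, 0.2, 0.3, 0.4, 0.5), state)
minima = find_minima(pmf_1d(il, 0.5, state), prominence=0.08, min_count=200)
print(f"ionic-lock minima   : {[round(m, 2) for m in minima]} angstrom")
print(f"bin-size spread     : {report.max_deviation:.2f} kcal/mol")
```

Output:

```
true barrier        : 1.96 kcal/mol
boosted (apparent)  : 0.80 kcal/mol
after reweighting   : 1.95 kcal/mol
ionic-lock minima   : [4.75, 6.25, 14.25] angstrom
bin-size spread     : 0.13 kcal/mol
```

The boost cuts the apparent barrier from 1.96 to 0.80 kcal/mol (that is the
acceleration), and exponential reweighting recovers the true profile to
within sampling noise.  The synthetic ionic-lock series shows its three
free-energy minima — closed (≈4.6 Å), water-bridged (≈6.4 Å) and the broad
open state (≈14.2 Å) — at the 0.5 Å bin centres, with a 0.13 kcal/mol
maximum spread across the five bin sizes, i.e. converged sampling.

## Command line

`amdkit` exposes `simulate`, `rc`, `pmf`, `reweight`, `sweep` and
`fixtures` subcommands driven by strict JSON configs; every run writes a
manifest (seed, parameters, config hash) and stamps the hash into each
output file, so runs are byte-reproducible.  `amdkit fixtures` emits the
synthetic structure fragment and reaction-coordinate series used throughout
the tests.

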