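# pmfpath

Free-energy and kinetics post-processing for umbrella-sampling studies of
ion permeation — the analysis chain that turns biased collective-variable
(CV) time series into a potential of mean force (PMF), a minimum
free-energy path (MFEP), and relative ion-conduction rates.

It is written for people who study permeation through channel pores (for
example K⁺ and Na⁺ moving through a selectivity filter) with harmonically
restrained umbrella windows over one or two ion-position CVs, and who then
want to go from raw window samples all the way to "system A conducts X
times faster than system B" without leaving Python.

## What it computes

1. **WHAM** (`pmfpath.wham`) — biased window histograms are combined into an
   unbiased PMF by the weighted histogram analysis method,

       p_b = Σ_k n_kb / Σ_k N_k exp[(f_k − c_kb)/k_BT],
       f_k = −k_BT ln Σ_b exp(−c_kb/k_BT) p_b,

   iterated to self-consistency (default 100 bins per CV, tolerance 10⁻⁶
   kJ/mol on max |Δf_k|), with F = −k_BT ln p normalized to a zero minimum.
   The bias convention is U = ½k(z−z⁰)² per CV.
2. **Surface tools** (`pmfpath.surface_tools`) — bicubic interpolation of
   the PMF grid (optionally with noise-calibrated smoothing), local-minimum
   detection with persistence pruning, and basin assignment of samples by
   coarse gradient descent (the "snapshot clustering" step).
3. **MFEP** (`pmfpath.mfep`) — nudged-elastic-band (NEB) snippets between
   all nearby minima (improved tangent, climbing image), joined into
   candidate start→end paths, ranked by their highest energy, and projected
   onto arc length λ to give F(λ) with alternating valleys and peaks.
   `barrier()` measures directed barriers, including the cyclic re-entry
   barrier over the periodic boundary (the profile is continued without an
   energy shift, so re-entering the first state pays back the net drop).
4. **Rates** (`pmfpath.rates`) — each hop between neighboring valleys i, j
   gets an overdamped Kramers rate

       r_ij = ω(λ_i) ω(λ_j) / (2πγ) · exp(−ΔF‡_ij / k_BT),

   with ω = √|F″(λ)| from local cubic fits. Hops are chained into a linear
   master equation with the last state absorbing; the total rate is the
   inverse mean first-passage time. γ is taken identical across compared
   systems, so only *relative* rates are reported (γ ≡ 1 internally). When
   a chain's rate range overflows 64-bit arithmetic, the single-step rate
   over the highest forward barrier is reported as a flagged "≤" bound.
   Transition-state-theory helpers convert unitary conductance ↔ ion rate
   ↔ effective Eyring barrier.
5. **Synthetic landscapes** (`pmfpath.landscapes`) — Gaussian-mixture
   surfaces with exactly known minima, saddles and barriers, window
   planning (regular or adaptive below an energy cutoff), and seeded
   Metropolis sampling of the biased Boltzmann distribution. Every stage
   of the chain can therefore be validated against closed-form ground
   truth at desk scale.

Files are plain text throughout: COLVAR-style window files with a
`windows.meta` index, gridded `z1 z2 F count` PMFs, CSV tables for minima,
paths and profiles, and JSON rate reports.

## Worked example

The quick conversions first. The lowest single-channel conductance estimate
for a weakly selective pacemaker channel, 0.97 pS, carried by monovalent
ions at 100 mV driving force:

```sh
$ pmfpath tst --conductance 0.97 --voltage 100
rate: 6.054e+05 1/s (0.97 pS at 100.0 mV, 1.0 e/event)
Eyring barrier at 298.0 K: 40.00 kJ/mol
```

So ~6×10⁵ ions/s, which transition-state theory equates to one effective
barrier of 40 kJ/mol — any barrier on the conduction path must stay below
this for the measured conductance to be possible.

Now a full pipeline run on a synthetic two-well landscape whose true
inter-well barrier is 13.13 kJ/mol:

```python
from pmfpath import landscapes, io

surface = landscapes.make_surface(
    [(-18.0, (-0.4, 0.0), (0.2, 0.2)), (-18.0, (0.4, 0.0), (0.2, 0.2))],
    domain=((-0.8, 0.8), (-0.4, 0.4)))

plan = landscapes.plan_windows(surface.domain, spacing=0.1)
windows = landscapes.sample_windows(surface, plan, force_constant=1000.0,
                                    n_samples=2000, seed=21)
io.write_windows("demo_windows", windows)

config = io.RunConfig(windows_dir="demo_windows", output_dir="demo_out",
                      force_tolerance=3.0, fit_window=0.12)
report = io.run_pipeline(config)
```

which prints (via the stage log) and returns:

```
windows: 153, minima: 2
recovered barrier: 14.15 kJ/mol
total rate (friction-scaled): 0.2388
```

153 windows of 2000 samples recover the two minima and the saddle to about
1 kJ/mol; the Kramers chain for the single hop gives the escape rate in
friction-scaled units — meaningful only as a ratio against another system
processed the same way (`pmfpath compare`). `demo_out/` now holds the PMF
grid, minima table, ranked path CSVs, the 1D profile, and `rates.json`.

The same stages are available as CLI subcommands (`generate`, `sample`,
`wham`, `minima`, `mfep`, `project`, `rates`, `compare`, `tst`, `waters`,
`run`), each reading the previous stage's text outputs.

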