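# ferrisim

Deterministic kinetic model of dynamic iron storage in ferritin, and of the
role ferritin plays in buffering the cytosolic labile iron pool (cLIP).

Ferritin is a 24-subunit protein nanocage that oxidizes Fe²⁺ at ferroxidase
sites and deposits it as a ferrihydrite mineral core of up to ~4,500 atoms
(~2,500 in practice before the protein precipitates). In cells it is the
main iron store, and — because both uptake and release are fast — it acts as
a chemical buffer that pins the cLIP at a low, nearly constant level over a
wide range of total cell iron. `ferrisim` implements a population model of
this process for quantitative exploration: steady-state iron-load
distributions, the buffering response to iron pulses and washouts,
calibration of the release rate, and the transform between simulated load
distributions and sucrose-gradient sedimentation profiles. It is aimed at
systems-biology and iron-homeostasis researchers who want a desk-scale,
fully reproducible counterpart to ferritin loading experiments.

## The model

Iron is lumped into packages of `Fe_pack = 50` atoms. A cage holding
`i = 0..N` core packages (`N = 50`, i.e. 2,500 atoms) is a distinct species
`Fn_i`; `C_i` is the Michaelis-type complex of `Fn_i` with one reversibly
bound package, and `Fe` is the free-package pool (the cLIP). All amounts are
per-cell picomoles; mass-action kinetics with

- association / dissociation: `Fn_i + Fe ⇌ C_i` (`k_aso`, `k_dis`),
- mineralization: `C_i → Fn_{i+1}` (`k_cat`; full cages do not mineralize),
- load-dependent release: `Fn_i → Fn_{i−1} + Fe` at the Hill-saturating rate

  `k_loss,i = k̃_loss · (1 + κ·iⁿ/(θⁿ + iⁿ))`  for `i ≥ 1`,

  which grows with the exposed mineral surface for small cores and
  saturates at `(1 + κ)·k̃_loss` when the exit pores are rate limiting,
- protein turnover: `Fn_i → Fn_0 + i·Fe` (`k_d`), with synthesis balancing
  degradation so total ferritin is constant.

The mass balances give a stiff system of `2N + 3 = 103` ODEs that conserves
total iron and total ferritin exactly; the package integrates it with an
implicit multistep (BDF) method and an analytic Jacobian. The default
parameter set (rates from in-vitro ferritin kinetics, amounts for Caco-2
cells) lives in `ModelParameters` and reproduces, among other things, a
steady-state cLIP equal to 5% of total cell iron at the reference loading of
1000 Fe atoms per cage.

## Worked example

```python
from ferrisim import (make_parameters, state_for_ratio, run_to_steady_state,
                      iron_distribution)

params = make_parameters()                      # published defaults, N = 50
state0 = state_for_ratio(1000.0, params)        # 1000 Fe atoms per cage, all free
result = run_to_steady_state(state0, params)

print(result.t_ss_h)                   # 0.0004095
print(result.clip_fraction_of_total)   # 0.049999976377879174
print(result.clip_packages * 50)       # 2.7599986960561165e-05
dist = iron_distribution(result.state, params)
print(dist.mean_load_atoms)            # 904.3977071852839
```

The system reaches steady state in ~4×10⁻⁴ h; 5.0% of the iron remains in
the cLIP (2.76×10⁻⁵ pmol/cell on the atoms basis) while ferritin stores the
rest at a mean load of ~904 atoms per cage.

The same experiments are available from the shell; every run writes CSV/JSON
results plus a `manifest.json` that fully reproduces it:

```
$ ferrisim --out demo pulse --multiple 20
cLIP change after 20.0x pulse: +13.1%

$ ferrisim --out demo stages --ratio 1000
cLIP settles by 0.0293, distribution by 0.0825 normalized time units
```

The 20× pulse doubles the total iron in the system, yet the steady-state
cLIP rises only 13.1% — the buffering behaviour the model was built to
expose. Other subcommands: `simulate` (normalized-time trajectory export),
`sweep` (steady states over iron:ferritin ratios), `washout`, `calibrate`
(tune `k̃_loss` to a target cLIP fraction), `sediment` (gradient-profile
transform using a fitted or synthetic calibration curve) and `sensitivity`.

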