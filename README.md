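# bnyg

Two-regime phase-separation model of **B**rownian **y**et **n**on-**G**aussian
diffusion, as a tested library, stochastic simulator, and CLI.

The model: long-range dispersion attraction between a colloidal particle and a
weakly interacting fluid drives a phase separation. In the gas-like regime the
particle undergoes overdamped diffusion with a constant-magnitude drift toward
the origin (dry friction), whose stationary law is a Laplace (double
exponential) displacement distribution with scale λ(t) = √(Deff·t). Past a
critical time tc the drift becomes negligible and the Laplace law relaxes
under free diffusion with the liquid-phase diffusivity — a Laplace⊛Gaussian
transition density that becomes Gaussian within seconds. The mean squared
displacement stays linear in time throughout, with the equal-weight average
diffusivity Davg = (DeffG + DeffL)/2.

## Layout

| module | contents |
| --- | --- |
| `bnyg.params` | physical constants, Stokes–Einstein diffusivity with extensional viscosity (kB·T/18πηR), the D/Z² compressibility algebra, and the Davg inversion |
| `bnyg.mechanism` | Lennard-Jones attraction, inverse-cube interface potential, linearized density profile, particle-number gradient, inter-cluster force |
| `bnyg.model` | dry-friction propagator, Laplace and Laplace⊛Gaussian densities (overflow-safe `erfcx` form), MSD, variance rescaling, Gaussianization time |
| `bnyg.simulate` | seeded Euler–Maruyama ensemble of the two-regime Langevin process, summary statistics, Davg recovery by MSD regression |
| `bnyg.oracle` | Crank–Nicolson diffusion solver (Rannacher startup, Dirichlet boundaries, mass guard) and direct-quadrature Gaussian convolution — independent ground truths for the closed forms |
| `bnyg.compare` | the worked colloidal-bead application (D ≈ 0.014 μm²/s, DeffL ≈ 0.79 μm²/s, Z_L ≈ 0.13, cholesterol control 0.012 μm²/s) and fixed-intercept regression scoring of user histograms |

## CLI

```sh
bnyg infer                          # D, DeffL, Z_L from the default config
bnyg pdf --time 5.8 --grid 4.0,801  # displacement density table (CSV)
bnyg pdf --time 5.8 --oracle ...    # + Crank–Nicolson sup-norm cross-check
bnyg gauss-time --threshold 0.05    # time past tc to reach Gaussianity
bnyg simulate --n 1000 --tmax 4 --seed 1 --out traj.csv
bnyg stats --in traj.csv --times 1.0,2.0
bnyg reproduce --out report.json    # full worked application + model curves
bnyg compare --model-time 0.06 --data hist.csv --diameter 0.1
bnyg mechanism --config cfg.yaml --rmax-nm 500
```

Configs are YAML with `physical:` (`temperature_C`, `water_viscosity_mPas`,
`viscosity_multiplier`, `radius_nm`), `phase:` (`Davg_um2s`, `tc_s`, `Z_G`)
and, for `mechanism`, `mechanism:` (`epsilon_J`, `sigma_nm`, `rho_s`, `rho_L`,
`radius_nm`) blocks. Omitting `--config` uses the built-in bead-on-bilayer
parameters (22 °C, 100× bulk-water viscosity, R = 50 nm, Davg = 0.40 μm²/s,
tc = 4 s). Histogram CSVs have columns `x_over_d,log10_density,time_s`.

## Conventions

- Bulk-water viscosity reference: 1.0 mPa·s (documented assumption;
  configurable via `water_viscosity_mPas`).
- All diffusivities in μm²/s, lengths μm, times s outside `bnyg.params`;
  SI internally there, converted exactly once at the boundary.
- Externally visible densities are variance-rescaled to 2·Davg·t; the
  internal Laplace scale convention is λ(t) = √(Deff·t) and is unobservable
  after rescaling.
- The simulator is parameterized by (Deff, λ(t)) only — drag and microscopic
  diffusivity enter solely through their observable ratio. Drift updates
  adiabatically, floored at λ(10·dt); regimes are assigned per path,
  permanently, with probability ½ each.
- Gaussianity criterion: excess kurtosis 3·(2λ0²)²/(2λ0² + 2·DeffL·t′)²
  below a configurable threshold (default 0.05).
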