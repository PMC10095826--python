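# ffmatch

Desk-scale pipeline for recalibrating bonded force-field terms by generalized
energy/force matching against a reference Hamiltonian, and for analysing
host–guest binding through contact-number collective variables, well-tempered
metadynamics, free-energy surfaces and standard-state binding free energies
with error/ranking metrics.

Because the original workflow depends on external QM/MD engines, every input
here is synthetic and exactly known: a "ghost" parameter set labels sampled
configurations with reference energies/forces (so parameter-recovery has a
ground truth), toy potentials have quadrature-exact free energies, and the
reference binding-affinity table ships as a packaged text fixture.

## Layout

| module                | contents |
|-----------------------|----------|
| `ffmatch.mm`          | topology/parameter model, analytic MM energies and forces (harmonic bonds/angles, periodic torsions and impropers, LJ + Coulomb with 1-2/1-3 exclusions and scaled 1-4), symmetry classes |
| `ffmatch.fitting`     | simultaneous energy/force-matching objective with L2 regularization toward the start parameters, bounded quasi-Newton fit, error assessment and force-error classification |
| `ffmatch.sampling`    | overdamped Langevin integrator, well-tempered metadynamics (default height 0.24 kcal/mol, pace 0.5 ps, bias factor 20), FES-from-bias and final-bias reweighting |
| `ffmatch.cvs`         | switching-function contact numbers (r0 = 6 Å, heavy-atom convention) with by-atom decomposition, contact-map classification, radius of gyration, COM spherical CVs |
| `ffmatch.thermo`      | histogram free-energy surfaces, global-minimum / zero-contact decoupled states, two-term standard-state binding ΔG° (V° = 1660.54 Å3), block-analysis SD |
| `ffmatch.metrics`     | affinity tables, G5 protonation averaging, MSE/MAE/RMSE, Kendall τ, Pearlman predictive index |
| `ffmatch.synthetic`   | toy macrocycle host generator, ghost-Hamiltonian reference datasets, toy binding samples with quadrature-exact ΔG°, packaged affinity-table fixture |
| `ffmatch.io`          | plain-text formats: multi-frame XYZ, topology/parameter YAML, labelled datasets, FES grids, hills files, index groups |

Units: kcal/mol, Å, radians, amu; k_B = 0.0019872041 kcal/(mol·K).

## CLI

```bash
ffmatch fixtures out/                 # packaged affinity table + toy host
ffmatch genref out/toy_host.yaml out/ref --frames 2000 --seed 1
ffmatch assess out/ref out/toy_host.yaml
ffmatch fit out/ref out/start.yaml out/fitted.yaml
ffmatch simulate sim.yaml out/run    # Langevin / metadynamics on a toy potential
ffmatch contacts traj.xyz groups.ndx contacts.tsv
ffmatch cvs traj.xyz groups.ndx system.yaml cv.tsv
ffmatch fes cv.tsv surface.fes --columns rho,C_total
ffmatch bindfe surface.fes --contact-threshold 0.01 --rho-min 8.5
ffmatch metrics table1.tsv
```

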