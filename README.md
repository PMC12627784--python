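# idpscale

Conformational scaling of intrinsically disordered protein (IDP) regions
across assembly states — monomer, nanocluster, condensate — from
single-molecule FRET bursts, donor fluorescence-lifetime (FLIM-FRET)
decays, FCS diffusion data and residue-level coarse-grained simulations.

Disordered regions of phase-separating proteins (for example the
FG-repeat-rich domains of nucleoporin fusion oncoproteins) change their
compactness as molecules move from dilute solution into oligomeric
nanoclusters and dense condensates. `idpscale` implements the full analysis
chain that turns raw photon data and bead trajectories into the statistic
that summarises this: the apparent Flory exponent ν of

    R_E = ρ₀ · N_res^ν,

where R_E is the root-mean-square distance between two labelled residues
separated by N_res positions (ν ≈ 1/3 collapsed, 1/2 ideal, ≈ 0.6
expanded). Distances come from a Gaussian-chain model of the inter-dye
distance distribution: either by inverting the mean transfer efficiency
⟨E⟩ = ∫ E(r)P(r)dr (intensity route) or by Poisson maximum-likelihood
fitting of the donor decay
I(t) = {A_D e^(−t/τ_D) + A_FRET ∫P(r)e^(−(t/τ_D)[1+(R₀/r)⁶])dr + A_bg·bg(t)} ⊗ IRF
(lifetime route, immune to acceptor quenching and background-heavy
condensates).

The package is organised by data type:

| module | contents |
|---|---|
| `idpscale.polymer_fret` | Gaussian chain, E(r), ⟨E⟩ ↔ R_E inversion, scaling-law fits |
| `idpscale.burst_fret` | all-photon burst search, corrected E/S, 2D population fits |
| `idpscale.decay_flim` | decay forward model, background/postbleach fits, MLE R_E, bootstrap global ν, phasors |
| `idpscale.fcs_diffusion` | multi-tau correlator, 3D diffusion fits, Stokes–Einstein, repeat-measurement distributions |
| `idpscale.cg_sim` | HPS-Urry coarse-grained force field, BAOAB Langevin dynamics, staged equilibration, sequence profiles |
| `idpscale.traj_analysis` | chain clustering, radial block densities, contact maps, n_eff/SEM machinery, Flory fits |
| `idpscale.synthetic_data` | ground-truth generators for every input (decays, bursts, FCS traces, conformers, micelles) |
| `idpscale.io`, `idpscale.cli` | plain-text formats and the `idpscale` command-line tool |

## Worked example

Generate a synthetic in-cell-style dataset (five labelling variants, thirty
cells each, true ν = 0.61) and recover the exponent with the bootstrap
global fit:

```python
from idpscale import decay_flim as df, synthetic_data as sd

nu_true, rho0 = 0.61, 0.55
data = {}
for N in (62, 91, 120, 146, 170):
    decays = [sd.gen_decay(sd.DecaySpec(re_nm=rho0 * N**nu_true,
                                        a_fret=0.7, a_bg=0.3,
                                        total_photons=30_000,
                                        seed=N * 1009 + c))[0]
              for c in range(30)]
    data[f"N{N}"] = (N, decays)

template = sd.decay_model_from_spec(sd.DecaySpec())
res = df.bootstrap_global_nu(data, template, frac=0.7, rounds=10, seed=7)
print(f"nu = {res.nu_mean:.3f} +/- {res.nu_sd:.3f}")
```

Output:

```
nu = 0.613 +/- 0.003
```

Each bootstrap round resamples 70% of the cells per variant, sums their
decay histograms and fits all variants globally with shared (ρ₀, ν); the
recovered mean matches the planted exponent, and the round-to-round spread
is the cellular-heterogeneity error bar. The same machinery applied to a
single decay, `df.fit_decay_mle(hist, template)`, returns the per-sample
R_E in nm.

A second one-liner, from the simulation side: `tests/conftest.py` defines a
42-residue amphiphilic diblock (aromatic-rich hydrophobic block, charged
hydrophilic block); running it as 1, 5 and 10 chains
(`run_diblock_sim`) and fitting mean inter-label distances gives a ν that
increases with cluster size — the chain-expansion-on-assembly trend — and
radial density profiles whose charged block sits at larger radius than the
hydrophobic block (micelle-like architecture).

The CLI mirrors the library: `idpscale synth decay`, `idpscale bursts`,
`idpscale fit-decay`, `idpscale global-nu`, `idpscale fcs`,
`idpscale simulate`, `idpscale analyze-traj`, `idpscale phasor`.

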