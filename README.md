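# rdcsampler

Back-calculation of residual dipolar couplings (RDCs) for rigid protein
structures, by two routes:

* **AT** — the standard alignment-tensor (Saupe matrix) approach: an
  unweighted linear least-squares fit of the five independent components
  of the symmetric traceless order matrix S to a set of target couplings,
  `D_k = Dc_k R_k u_kᵀ S u_k`.
* **HRS** — magnetic-field rotational sampling: Langevin stochastic
  dynamics of a two-particle "magnetic-field vector" (two 15.035 u united
  atoms on a rigid 0.153 nm bond, 308 K, friction 2.4 ps⁻¹, Δt = 2 fs)
  under flat-bottom restraints on the exponentially memory-averaged
  couplings, which biases the sampled orientation distribution toward one
  reproducing the targets without assuming its functional form. Reported
  couplings are plain time averages `Dc_k R_k ⟨P2(cos θ_k)⟩` over all
  runs.

The package is aimed at NMR/structural-bioinformatics users who want to
ask how well a set of measured backbone RDCs (N–Hᴺ, Cα–Hα, Cα–C′, C′–N)
is reproduced by a given X-ray structure, how sensitive the calculated
values are to the choice of restraint set, and whether the fitted
orientation distribution shows magic-angle artifacts. Because an RDC is
defined through an unknown, immeasurable orientation distribution that
both methods *fit* to the targets, calculated values depend on the target
set — the evaluation metrics (RMSD/rRMSD/urRMSD, deviation counts,
cross-method and cross-structure RMSDs) and the θ/sin θ orientation
diagnostics quantify exactly that.

It also ships a first-class synthetic-fixture generator (ideal helical
backbones; targets from a known alignment tensor, optionally noisy), so
the whole pipeline is verifiable with no external data: a noise-free
generate-then-fit loop must recover the tensor exactly, and restrained
rotational sampling must pull the reported couplings into the flat-bottom
window of the same targets.

## Worked example

Generate a 30-residue ideal helix with noise-free targets from a known
tensor, fit the tensor back, run restrained rotational sampling, and
compare the two methods:

```
$ rdcsampler synth --n 30 --sigma 0 --seed 1 --out-pdb helix.pdb --out-rdc rdc.tsv
wrote 30-residue helix and 118 targets (sigma=0.0 Hz, seed=1)

$ rdcsampler at-fit --pdb helix.pdb --rdc rdc.tsv --restrain-set NCAH160 --out at.json
AT fit: rRMSD = 0.01 Hz over 59 restraints

$ rdcsampler hrs-run --pdb helix.pdb --rdc rdc.tsv --restrain-set NCAH160 \
      --steps 5000000 --runs 3 --seed 7 --out hrs.json     # 3 x 10 ns
HRS: rRMSD = 0.65 Hz (3 runs x 5000000 steps)

$ rdcsampler compare --calc at.json --calc2 hrs.json --out cmp.tsv
cross-RMSD(all) = 0.460 Hz

$ cat cmp.tsv
bond_class	n	cross_rmsd_hz
C-N	29	0.0528
CA-C	30	0.0564
CA-HA	30	0.8611
N-HN	29	0.2961
all	118	0.4599
```

Reading the numbers: the AT fit reproduces noise-free synthetic targets
essentially exactly (rRMSD 0.01 Hz — the only error is the 10⁻⁴ nm
coordinate rounding of the PDB format), and the recovered tensor matches
the generating components (5.0, −2.0, 3.0, −1.5, 2.5)·10⁻⁴. The HRS
residual is a *sampling* error: it shrinks with simulation length (with
`--steps 500000`, i.e. 3 × 1 ns instead of 30 ns, the same fixture gives
rRMSD = 8.0 Hz), and the per-class cross-RMSDs between the two methods
sit at a fraction of a Hz at full sampling. The restrain-set names
(`CAH59`, `NH101`, `NCAH160`, and the sequence-inverted artificial
variants `CAH59I`, `NCAH160I`) select which coupling types are restrained;
all four types are always predicted and scored, so the unrestrained
Cα–C′ and C′–N couplings act as a cross-validation set (`urRMSD`).

`rdcsampler report` writes a per-coupling table (residue, type, target,
one column per calculation, 3 Hz deviation flags), and the analysis module
provides θ/sin θ orientation histograms with magic-angle detection,
backbone superposition with per-residue displacement profiles, and
hydrogen-bond detection for structure comparison.

To score a real structure, supply its PDB file and a TSV of measured
couplings (`residue`, `bond_class`, `d0_hz`, optional second measurement
column `d0_hz_2`, which is averaged in); amide and virtual Hα protons are
constructed automatically.

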