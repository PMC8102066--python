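# dimerlens

Quantitative analysis of transmembrane-domain (TMD) dimerization in
seven-helix receptors (class C GPCRs such as the group II metabotropic
glutamate receptors), combining four complementary readouts in one tested
pipeline:

1. **Interface kinetics from coarse-grained trajectories.**  Each frame of a
   two-protomer bead trajectory is labeled by the ordered pair of domain
   sets (helices TM1–TM7, loops, termini) that form more than 20 residue
   contacts with the partner protomer, using a 1.0 nm cutoff on the minimal
   bead–bead distance per residue pair.  The resulting microstate
   trajectory feeds a Markov state model (MSM) at lag τ: transition matrix
   `P_τ`, stationary distribution `π`, implied timescales
   `t_i = −τ / ln λ_i`, and a *dimeric fraction* (total stationary weight of
   non-monomeric states).  PCCA+ aggregates microstates into metastable
   macrostates with probabilities `π_I = Σ_{i∈I} π_i`, helix-interface
   profiles `p_{D,α,I} = Σ_{i∈I, D∈l_iα} π_i / π_I` (domains with
   p ≥ 0.4 form the macrostate label), and membership-averaged contact
   matrices `C_{DD'}^I`.  Transition path theory yields committors and
   reactive flux between interface classes (labels identified up to
   protomer swap, loops ignored), and Jarzynski's equality
   `ΔF = −kT ln ⟨e^{−W/kT}⟩` converts steered-pull work samples into
   relative free energies.
2. **Single-molecule pulldown (SiMPull) subunit counting.**  Photobleaching
   step-count distributions per movie, percent dimerization by min-max
   normalization (`(observed − 5) / (55 − 5) × 100`, anchored to
   fluorescence background and an obligate full-length dimer), ligand
   condition comparisons, and two-color pulldown ratios.
3. **FRET / calcium response quantification.**  FRET index
   `I_A / (I_D + I_A)`, window responses normalized to saturating agonist,
   and four-parameter logistic (Hill) concentration–response fits.
4. **Chemical-class sequence conservation** over residue subsets of a
   multiple sequence alignment (six side-chain chemistry classes).

A seeded `synthetic` module generates inputs with the exact statistical
structure each stage assumes (metastable chains, geometric toy dimers with
scheduled interfaces, binomially labeled monomer/dimer mixtures, Hill dose
responses, planted alignments, Gaussian work), so the full pipeline is
testable offline.

## Worked example

```python
import numpy as np
from dimerlens.synthetic import build_toy_dimer
from dimerlens.contacts import discretize_trajectory
from dimerlens.msm import count_transitions, estimate_msm, dimeric_fraction

# a scripted trajectory: 60% TM4|TM4 interface, 15% TM6|TM6, 25% monomer
schedule = [("TM4|TM4", 60), ("monomer", 25), ("TM6|TM6", 15)] * 8
topology, traj, truth = build_toy_dimer(schedule, seed=11)

dtraj = discretize_trajectory(traj, topology)
print({sid: str(lab) for sid, lab in dtraj.label_dict.items()})
# {0: '(TM4|TM4)', 1: '(-|-)', 2: '(TM6|TM6)'}

msm = estimate_msm(count_transitions([dtraj.state_ids], 1), 1.0, 1,
                   reversible=False)
print(round(dimeric_fraction(msm, dtraj.label_dict), 3))
# 0.755
```

The three microstates are the two scheduled dimer interfaces plus the
monomeric state `(-|-)`; the dimeric fraction recovered from the MSM's
stationary distribution (0.755) matches the scheduled 75% of frames in
contact to within sampling error.

The same stages are scriptable from the shell:

```sh
dimerlens discretize --topology top.json --traj traj.xyz --out states/
dimerlens msm --states states/ --lag-ns 20 --out msm.json
dimerlens simpull --spots spots.tsv --min 5 --max 55 --out dimerization.tsv
dimerlens crc --dose dose.tsv
dimerlens conserve --aln aln.fasta --subsets subsets.json --out cons.tsv
```

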