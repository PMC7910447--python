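# accref

Protein model accuracy estimation and accuracy-guided refinement support.

Given a protein structure model, `accref` estimates — or, with a reference
native structure, computes exactly — three coupled quantities per residue
pair and residue:

- the **estogram**: a categorical distribution over the signed CB–CB distance
  error e = d_model − d_native, over 15 fixed bins with boundaries at
  ±0.5, ±1, ±2, ±4, ±10, ±15, ±20 Å;
- the **mask**: the (probability of the) native CB–CB distance being below
  15 Å (CA substitutes for CB at glycine);
- the **CB l-DDT** score, reconstructed from estogram and mask without a
  native structure:

  ```
  lddt_i = 0.25 · (p̄0 + p̄1 + p̄2 + p̄3) / p̄4
  ```

  where p̄k is the mask-weighted mean probability (over partners j ≠ i) that
  |e_ij| is within 0.5/1/2/4 Å, and p̄4 is the mean mask probability.

These predictions drive a refinement support layer: confidence-classified
pair restraints (flat-bottom bounded wells, sum-of-sigmoid wells, log-odds
estogram spline potentials, and a simplified contact potential), unreliable-
region selection for intensive resampling, evolutionary pool scheduling with
recombination, final-model selection by predicted global l-DDT with
structural averaging, and accuracy-derived B-factors
(B_i = 8π²u_i²/3 with u_i = 1.5·exp[4·(0.7 − lddt_i)]) for molecular
replacement.

The package includes a trainable residual network over rotation-invariant
features (per-residue 3D voxel grids in backbone local frames, tiled 1D/2D
features, a 20-block dilated 2D trunk with two output arms), an exact/corrupted
oracle estimator for native-aware testing, and a synthetic generator of toy
natives and decoys at controllable accuracy. Everything runs on CPU at desk
scale.

## Worked example

Generate a toy native with decoys, score one against the native, turn its
oracle accuracy prediction into Rosetta-style restraints, and select
unreliable regions:

```
$ accref synth -n 40 --count 3 --magnitude 20 --seed 11 -o demo
wrote native + 3 decoys to demo

$ accref score -m demo/decoy_000.pdb -n demo/native.pdb
{"global": 0.8809, "gdt_ts": 76.25, "s_score": 0.8728, ...}

$ accref predict -m demo/decoy_000.pdb --native demo/native.pdb -o demo/pred.h5
{"global_lddt": 0.8809, "out": "demo/pred.h5"}

$ accref restraints -m demo/decoy_000.pdb -p demo/pred.h5 -o demo/decoy_000.cst
{"n_restraints": 753, "out": "demo/decoy_000.cst"}

$ head -2 demo/decoy_000.cst
AtomPair CB 1 CB 2 BOUNDED 4.295 6.295 1.000 0.5 acc
AtomPair CB 1 CB 3 BOUNDED 6.252 8.252 1.000 0.5 acc

$ accref regions -p demo/pred.h5
{"mode": "static", "selected": [0, 1, 2, 3, 4, 5], "fraction": 0.15}
```

The decoy preserves 88% of its native CB environment (global l-DDT 0.88) and
76 GDT-TS; the oracle prediction reproduces the true l-DDT exactly; 753 pair
restraints are emitted (confident pairs as bounded wells centred on the
current distance, nonpreserving pairs as estogram-derived spline potentials);
and the 15% least reliable residues — here the first six, a perturbed
segment — are flagged for rebuilding. `accref refine-demo` runs the full toy
protocol (diversification, 10 pool iterations with recombination every
fifth, dual default/aggressive restraint trajectories, final structural
averaging) on such a pair.

Library use mirrors the CLI: `accref.metrics.cb_lddt`,
`accref.oracle.oracle_predict`, `accref.restraints.build_restraints`,
`accref.refinement.run_demo_refinement`, `accref.nn.AccuracyNetwork`.

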