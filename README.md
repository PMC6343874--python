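# craniofit

Statistical craniofacial reconstruction: given the skull of an unknown
individual, estimate a plausible head (skin) surface.  The package is
aimed at forensic and anthropological tool builders and at researchers in
statistical shape modelling who need a complete, automatic, testable
pipeline rather than interactive sculpting.

The method rests on three statistical models learned from corresponding
skull/skin surface pairs:

* a **volumetric skull model** `S(a) = s̄ + U a` — PCA over tetrahedral
  skull templates non-rigidly registered to each training skull with a
  tetrahedron volume-preservation energy
  `E(S) = E_fit(S) + λ_reg · Σ_T (vol(T(S)) − vol(T(S_prev)))²`;
* a **surface head model** `H(b) = h̄ + V b` — PCA over head templates
  registered with a rotation-compensated per-edge Laplacian bending energy
  `E_reg = Σ_e A_e ‖Δ_e h − R_e Δ_e h_prev‖² / Σ_e A_e`;
* a **dense soft-tissue-thickness (FSTT) statistic and model**
  `FSTT(c) = t̄ + W c` — the per-vertex shortest distance from each fitted
  skull vertex to the subject's skin, masked by a 2 mm data-support rule
  and aggregated into per-vertex mean/std/count.

Reconstruction fits the skull model to the remains (closed-form similarity
alignment alternated with Tikhonov-regularized PCA weights,
`λ_tik Σ_k (w_k/σ_k)²`, then non-rigid refinement), attaches thickness as
a **sphere model** — one sphere per skull vertex with the FSTT value as
radius, whose union's outer envelope approximates the skin — and fits the
head model to the sphere samples, weighting points on the outer envelope
by `w = 1 + 10⁸·‖h−q‖/B` so they dominate the interior ones.  Nose, ears
and calvaria, which have no overlying bone data, are completed by the
statistical prior.

Because clinical CT databases cannot be redistributed, the package ships a
first-class synthetic-anatomy module: skull/skin template pairs with known
low-rank population variation and known ground-truth thickness fields,
against which every stage is validated end to end.

## Worked example

```python
import numpy as np
import craniofit as cf
from craniofit import synthetic_anatomy as sa

# synthetic study population with known ground truth
templates = sa.make_template_pair(subdivisions=3)
spec = cf.PopulationSpec(n_subjects=10, rank=3, seed=42)
population = cf.make_population(spec, templates)

# build the three models
fitted_skulls = cf.fit_skull_population(
    templates.skull, [s.skull_surface for s in population])
fitted_heads = cf.fit_head_population(
    templates.head, [s.skin_surface.as_pointset() for s in population])
skull_model = cf.build_skull_model(fitted_skulls)
head_model = cf.build_head_model(fitted_heads)
statistic, per_subject = cf.build_fstt_statistic(
    fitted_skulls, [s.skin_surface for s in population])

# reconstruct a held-out subject from its skull alone
held = sa.make_subject(templates, sa.make_mode_basis(templates, 3),
                       np.array([3.0, -2.0, 1.0]), seed=7)
config = cf.ReconstructionConfig(skull_template=templates.skull,
                                 head_template=templates.head)
result = cf.reconstruct(held.skull_surface, skull_model, head_model,
                        statistic, config)
rmse = cf.head_rmse(result.fitted_head, held.skin_surface)
print(f"facial fit error: {np.mean([cf.surface_distances(f.boundary(), s.skull_surface.vertices).mean() for f, s in zip(fitted_skulls, population)]):.2f} mm")
print(f"reconstruction RMSE vs true skin: {rmse:.2f} mm")
```

Output:

```
facial fit error: 0.04 mm
reconstruction RMSE vs true skin: 0.50 mm
```

The first number is the mean distance from the training skulls to their
fitted templates (the registration tracks the target surface to a few
hundredths of a millimetre at this mesh resolution).  The second is the
distance between the reconstructed head — estimated from the skull and the
*population mean* thickness only — and the subject's actual skin; it is
dominated by how much this subject's soft tissue deviates from the
population mean, which is exactly what reconstruction from a mean
statistic cannot know.  Supplying the subject's true thickness instead
(`cf.reconstruct(..., held.true_fstt, config)`) drops the RMSE to the
envelope-approximation floor (0.11 mm on this subject).

A command-line interface mirrors the library:

```sh
craniofit simulate --out pop/ --n-subjects 10 --seed 42
craniofit build-skull-model --population pop/ --out skull.h5
craniofit build-head-model  --population pop/ --out head.h5
craniofit build-fstt        --population pop/ --out fstt.h5
craniofit reconstruct --skull remains.ply --skull-model skull.h5 \
    --head-model head.h5 --fstt fstt.h5 \
    --template-skull pop/template_skull.mesh --template-head pop/template_head.ply \
    --out recon/ --fstt-grid "c1=-2,0,2;c2=-2,0,2"
```

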