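# uedopt — uniform experimental design for discrete hyperparameter search

`uedopt` tunes the discrete settings of an expensive black-box objective —
the motivating case is the architecture hyperparameters of a small
convolutional network classifying benign vs. malignant breast-histopathology
image patches — with far fewer evaluations than a factorial sweep.  It
implements the uniform-experimental-design (UED) workflow end to end:

1. **Design.** Build or load a U-type uniform design table U_n(q^s): an
   n-run, s-column table whose every column is a permutation of levels
   1..q (with q = n).  Tables are scored by the squared centered
   L2-discrepancy (CD²) and squared wrap-around L2-discrepancy (WD²) of
   their midpoint-normalized point set — smaller means more uniform.  New
   tables come from the good-lattice-point rule
   `u_ij = ((i·h_j − 1) mod n) + 1` over generators h coprime to n,
   refined by a seeded level-swap descent on CD².
2. **Allocate.** Collapse each q-level column onto a mixed 2/3-level factor
   with the balanced pseudo-level rule `ceil(u·q′/q)` and substitute the
   factor's actual level values, yielding the runnable experiment plan.
3. **Run.** Evaluate a pluggable objective at every (run, replicate) cell
   with stable per-cell seeds, and average replicates into per-run means.
4. **Fit.** Regress the means on a polynomial response surface in the
   [−1, 1]-coded factors

   Y = α₀ + Σᵢ α₁ᵢXᵢ + Σᵢ α₂ᵢXᵢ² + Σᵢ α₃ᵢXᵢ³ + Σᵢ<ⱼ α₄ᵢⱼXᵢXⱼ + ε,

   with structurally collinear terms pruned (Xᵢ², Xᵢ³ for 2-level factors;
   Xᵢ³ for 3-level factors) and the rest entered by hierarchical forward
   stepwise selection under Mallows' Cp (pure error from replication) or
   BIC, capped at n − 2 coefficients.
5. **Recommend.** Enumerate the full discrete level grid (1296 points for
   the default eight factors), predict each candidate, and return the
   argmax, plus an improvement report against the best observed run.

The tables of the motivating 17-run study are packaged as fixtures: the
U₁₇(17⁸) design, its eight conv1/conv2 factors (kernel size, filter count,
stride, padding), the executed 17×8 plan, and the observed 17×3 accuracy
replicates.  A companion module does the convolutional shape arithmetic
(`floor((w − k + 2p)/s) + 1` per layer, same-padding `(k − 1)/2`, floor
pooling) to decide feasibility of any factor combination; actually training
on images is an optional plugin interface and is not required anywhere.

## Worked example

Score the packaged design and run the full fixture pipeline:

```sh
$ uedopt design --builtin u17_8
U17(17^8): 17 runs x 8 columns
cd2 = 0.061559
wd2 = 0.334480
```

CD² = 0.061559 and WD² = 0.334480 are the uniformity scores of the 17-run
table; they say the table spreads its 17 points over the 8-dimensional
level space nearly as evenly as is achievable at this size.

```sh
$ cat cfg.yaml
objective: fixture
confirmed_value: 84.41
outdir: out
$ uedopt pipeline --config cfg.yaml
best observed run: 2 (mean 83.40)
recommended settings: conv1_Kernel size=3, conv1_Filter=4, conv1_Stride=1, conv1_Padding=0, conv2_Kernel size=3, conv2_Filter=32, conv2_Stride=2, conv2_Padding=0
predicted response at recommendation: 84.34
grid size evaluated: 1296
best observed mean (run 2): 83.40
confirmed recommended response:  84.41
improvement:                     +1.01
```

Reading the output: the best run actually executed in the packaged study
reached 83.40% mean validation accuracy (run 2); the fitted response
surface predicts that an off-design combination would do better
(84.34% predicted); and if an external confirmation experiment of the
recommended settings measures 84.41%, the design-plus-surrogate loop
improved on the best in-design run by 1.01 percentage points.  The bundle
directory additionally receives the plan, responses, model JSON,
recommendation JSON and an echoed config.

The same workflow is available as a library:

```python
import uedopt

design = uedopt.builtin_u17_8()
plan = uedopt.builtin_plan_table6()
responses = uedopt.builtin_responses_table7()
results = uedopt.ResponseSurface.from_response_table(responses).fit()
print(results.summary())
print(results.recommend())
```

Synthetic benchmark surfaces with a planted optimum
(`uedopt.make_synthetic_surface`) let you exercise the whole loop with a
known ground truth; see `docs/methods.md` for the model, defaults and what
the benchmark does and does not demonstrate.

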