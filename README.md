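# crossdistill

Cross-modal knowledge distillation for **sensor upgrades**: train a classifier
on a new, richer sensor modality from very little labeled data by letting a
frozen network trained on the *old* modality supervise it.

When an imaging sensor is replaced (grayscale → color, white-light →
multispectral dermoscopy), the large dataset that powered the original
classifier does not transfer, and collecting and labeling a comparable
dataset in the new modality takes years. If the transition period yields
even a small set of *paired* samples — the same scene captured by both
sensors — the original network can serve as a **teacher**: its
temperature-softened class probabilities on the old modality become soft
targets for a **student** network reading the new modality.

## The objective

For logits $z$ and temperature $T > 0$, the softened class distribution is

$$p_i(z, T) = \frac{\exp(z_i / T)}{\sum_j \exp(z_j / T)}.$$

With teacher logits $z_t$ (no gradient), student logits $z_s$ and one-hot
label $y$, the student minimizes the convex combination

$$L = \alpha\, L_D + (1 - \alpha)\, L_S, \qquad
L_D = -\sum_i p_i(z_t, T) \log p_i(z_s, T), \qquad
L_S = -\sum_i y_i \log p_i(z_s, T_{\mathrm{eff}}),$$

where $T_{\mathrm{eff}}$ is either $T$ (`paper_literal`, the default) or 1
(`unit_temperature`, the convention of the classical distillation
literature). Two extensions are provided:

* **α-annealing** — $\alpha$ decreases linearly from $\alpha_0$ at
  iteration 0 to $\alpha_n$ at iteration $n-1$, so the teacher's influence
  fades as the student learns to exploit the new modality;
* **selective distillation** — after a bootstrap phase, examples the teacher
  misclassifies contribute only the hard-label term ($\alpha = 0$ for that
  example).

The package also builds the dual-modality benchmarks these ideas are
evaluated on: **2cMNIST** (digits colored with two luminance-matched colors,
`#61a4e4` / `#0aef46`, both BT.601 luminance 151.263, so the color channel is
invisible in grayscale), a grayscale/color CIFAR-10 pairing, long-tail
imbalance samplers (linear 1.00→0.50 for the teacher, quadratic $(1-i)^2$
for the student), and a fully synthetic paired-modality shape fixture that
needs no downloads.

## Worked example

```python
from crossdistill.evaluation import ExperimentGrid, run_grid

grid = ExperimentGrid(experiment="synthetic", sizes=(10,), n_repeats=3,
                      base_seed=7)
result = run_grid(grid)
print(result.reference)
print(result.summary.to_string())
```

```
     condition         metric  value
0      teacher  test_accuracy  0.815
1      teacher  tail_accuracy  1.000
2  upper_bound  test_accuracy  1.000
3  upper_bound  tail_accuracy  1.000
   cell condition         metric      mean       std  count
0    10  baseline  tail_accuracy  0.462222  0.252132      3
1    10  baseline  test_accuracy  0.487333  0.078239      3
2    10   student  tail_accuracy  0.620000  0.214890      3
3    10   student  test_accuracy  0.548667  0.066199      3
```

The grayscale teacher reaches 0.815 (it cannot separate the two confusable
shape pairs), the color upper bound 1.000. With only **10** color training
images, the distilled student averages **0.549** against **0.487** for the
label-only baseline — the qualitative accuracy-vs-train-set-size result the
toolkit exists to demonstrate, at fixture scale.

The same study is available as scikit-learn estimators
(`ConvNetClassifier`, `DistilledStudentClassifier`) and from the shell:

```bash
crossdistill make-data --source synthetic --output ds/
crossdistill train --set role=teacher --output runs/teacher
crossdistill train --set role=student \
    --set teacher.checkpoint=runs/teacher/checkpoint.npz \
    --set distill.alpha=0.6 --set distill.temperature=8 --output runs/student
crossdistill reproduce synthetic --output results/synthetic
```

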