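# Methods

## Model

The generator is a single-layer GRU policy over a learned SMILES
vocabulary. Tokens are the symbols of the training corpus — bracket
atoms and the two-letter halogens `Cl`/`Br` are single tokens, every
other character is its own token — plus START, STOP and PAD. Generation
is autoregressive multinomial sampling at temperature 1.0, terminated by
STOP or truncated at `max_length` (longest corpus tokenization + 2). PAD
and START are masked out of the output softmax, so the emission
distribution is identical in training and inference modes; an immediate
STOP decodes to the empty string, which is treated as an invalid
molecule downstream.

The network is implemented in NumPy (float64) with hand-written
backpropagation through time. Supervised pretraining, the
policy-gradient loss and the replay loss are all instances of one
primitive — weighted next-token negative log-likelihood under teacher
forcing — with different weight matrices:

* pretraining / fine-tuning: uniform weights `1 / n_tokens`
  (mean per-token cross-entropy);
* policy gradient / replay: `w_i = r(s_N) · γ^i`, the whole-trajectory
  reward spread over transitions with the discount counted from the
  sequence start (`γ^1` on the first token). This start-anchored
  discount is unconventional — most formulations discount from the
  trajectory end — but it is the form of the objective implemented
  here, and the test suite pins it (a length-1 trajectory has loss
  `−r·γ·ln q`, not `−r·ln q`).

Gradients are exact; the suite checks every parameter of a small policy
against central finite differences at 1e-4 relative tolerance.

## Reward and heuristics

The reward is a threshold function of the predicted active-class
probability p(s): `r_pos` if `p(s) > p0` (strict), else `r_neg`;
unparseable strings receive `r_invalid`. The method itself does not
prescribe the reward values; the defaults `r_pos=10, r_neg=1,
r_invalid=0` keep a nonzero signal on valid-but-inactive molecules, so
an agent that never sees an active still optimizes validity rather than
receiving no feedback at all.

* **Reward shaping.** `p0` starts at 0.05 and rises by exactly 0.05
  whenever at least 15% (`≥`, not `>`) of a freshly generated evaluation
  batch scores strictly above the current `p0`. `p0` is non-decreasing
  and capped at `1 − increment` so the positive reward remains
  attainable. At full scale the evaluation batch is 3000 molecules; at
  toy scale the intermediate generation batch (one generation reused for
  buffer admission and shaping alike) is sized by config.
* **Experience replay.** The buffer stores unique canonical SMILES with
  their sampled trajectory and admission-time probability; admission
  requires validity and `p > p0` against the live threshold. Capacity
  defaults to 5000 with lowest-probability eviction (ties evict the
  oldest), keeping sampling probabilities well-defined. Replay draws are
  uniform without replacement. Replayed rewards are recomputed against
  the *current* threshold by default (`replay_reward_mode="current"`),
  so stored experiences track the rising bar; the stored admission-time
  reward is available as a config switch.
* **Fine-tuning.** Supervised cross-entropy on buffer draws — by
  construction identical to `pretrain_step` on the same batch, which the
  suite asserts to floating-point tolerance.

Buffer initialization strategies mirror the three studied conditions:
empty; `generated_actives` (sample the pretrained model, admit through
the predictor — the standard protocol); `external_library` (screen a
candidate list for strictly positive predicted probability, then drop
molecules whose Bemis–Murcko scaffold occurs in the predictor's training
chemistry — exact scaffold membership, not a similarity threshold).

## Predictor

Five random forests (100 trees each) trained on the five complements of
a stratified 5-fold split of a curated (canonical_smiles, label) table,
featurized as 2048-bit radius-2 Morgan fingerprints. The ensemble
prediction is the mean of member probabilities (`mean_probability`,
default). A `vote_fraction` mode — the fraction of members voting
active, necessarily quantized to fifths — ships as well: hard-label
averaging is what makes ensemble outputs land on the {0, 0.2, …, 1.0}
grid, and the two modes are not equivalent; neither is asserted to be
the "true" aggregation. Invalid SMILES score the sentinel 0 with a
logged warning (an unparseable molecule cannot be active).

## Curation

Raw activity records (compound id, SMILES, pChEMBL, assay type,
confidence score, organism) pass through, in order: (1) confidence ≥ 8,
assay type ∈ {binding, functional}, organism = Homo sapiens; (2)
canonicalization and grouping by canonical SMILES, invalid rows dropped
with a logged count; (3) exclusion of any compound whose replicate
pChEMBL spread exceeds one log unit; (4) collapse of surviving
replicates to their **median** (the representative-value rule is
config-visible; median is robust for the 2–3-replicate case); (5)
binarization at pChEMBL 6.0 (1 μM), boundary inclusive by default
(`boundary_active=True`; a compound at exactly 1 μM counts active) with
a flag to flip. The suite checks the survivor set against an
independent brute-force filter on randomized synthetic tables.

## Synthetic test bed

`generate_toy_corpus` assembles unique valid canonical SMILES from a
constrained fragment grammar (sulfur-free chains and rings over
C/N/O/F plus halogen/polar terminal groups; molecules are
prefix–ring–(linker–ring)–suffix concatenations, every candidate
re-validated through the chemistry backend). The "active" motif is a
thiophene ring, the only sulfur-containing fragment, so it occurs
exactly where planted: `round(corpus_size × motif_frequency)` molecules.
The substructure oracle scores motif-bearing molecules `p_hit=1`, others
`p_miss=0`, invalid strings 0 — a maximally clean stand-in for a QSAR
ensemble.

**Study conditions.** Corpus 1000 molecules, motif frequency 0.005.
At this frequency the pretrained model generates predicted actives at
~0.1–0.6% of valid-unique molecules and a pure policy-gradient run
admits essentially nothing to the buffer — the sparse-reward regime the
method targets. (At 2% the motif is findable by chance often enough
that plain REINFORCE latches onto it and the regime changes character.)
The pretrained generator is a hidden-128/embed-64 GRU trained 15 epochs
at Adam lr 2e-3, reaching ~78–81% valid samples. The RL learning rate
defaults to 1e-4: REINFORCE with the near-uniform `r_neg` reward is a
rich-get-richer process, and at aggressive rates it visibly
mode-collapses within a few hundred steps even with no activity signal,
which would confound the sparse-reward comparison; at 1e-4 the
tricks-free agent's valid-unique fraction stays near its pretrained
level across a 5-epoch run. γ defaults to 0.97, 32 trajectories per
policy step.

The scaled-down ablation runs 5 epochs with 300-molecule intermediate
generations and 1000-molecule final libraries; conditions without
replay use 25 policy iterations per epoch, conditions with replay use
15 (plus 10 replay), and fine-tuning conditions add 20 fine-tune
iterations; trick conditions start from a generated-actives buffer
(3000 samples screened at p0 = 0.05). Full-scale defaults
(20 epochs, 15/10/20, 3200/16,000-molecule generations, snapshots every
2 epochs) are the `TrainingSchedule` defaults.

**What the test bed does not emulate.** Real activity landscapes are
not single-substructure rules: predictor probabilities are continuous,
noisy and correlated with scaffold membership, and real corpora are
orders of magnitude larger and more diverse, with longer strings,
stereochemistry and charged species. Passing the toy-scale ordering
shows that the machinery extracts sparse rewards as designed, not that
any particular hit rate transfers to a real target. One toy-scale
departure from the full-scale observation is expected and reproduced in
our measurements: fine-tuning-only over-exploits the small initial
buffer, so its active fraction is high-variance and can exceed the
both-tricks condition on single seeds, while at full scale the
both-tricks condition is cleanly best; the suite therefore asserts the
robust pattern (tricks-free: highest valid fraction, near-zero active
fraction; fine-tuning-only: lowest valid fraction; both-tricks: high on
both axes).

## Evaluation

* `valid_fraction` = |valid ∧ unique| / total trajectories; uniqueness
  is by canonical SMILES **within the evaluated batch**, which is what
  detects mode collapse in a snapshot.
* `active_fraction` = |valid ∧ unique with p > 0.75| / |valid ∧ unique|,
  defined 0 for an empty valid-unique set. The 0.75 reporting cutoff is
  independent of the shaping threshold; the buffer admission threshold
  is wired to the live `p0` by default.
* Scaffold reports count Bemis–Murcko scaffolds of predicted actives,
  sorted by decreasing count with ties broken by canonical scaffold
  string; percentages are of all predicted actives, rounded half-up to
  one decimal. Acyclic molecules carry an explicit empty scaffold key.
* Similarity profiles report each library member's maximum Tanimoto
  (Morgan, 2048 bits, radius 2) to a reference set, with mean, median
  and a 10-bin histogram. Tanimoto of two all-zero fingerprints is
  defined as 0.

## Numerical and degenerate-input choices

* Emission probabilities are clipped at 1e-300 before `log`; losses are
  float64 throughout.
* A zero-reward batch applies no optimizer update (the gradient is
  exactly zero).
* `shaping_update` on an empty probability list logs a warning and
  leaves the state unchanged; replay or fine-tuning on an empty buffer
  raises, and the epoch driver skips those phases with a logged notice
  and a bookkeeping metrics row.
* External-library buffer entries whose SMILES contain symbols outside
  the generator's vocabulary cannot be replayed and are dropped with a
  logged count when trajectories are attached.
* Checkpoints (.npz: parameters + vocabulary + dimensions, versioned)
  and ensemble directories (one joblib per member + JSON manifest) are
  runtime artifacts, regenerated rather than shipped.

## Known limitations

* The stack-augmented memory variant of the generator is not
  implemented; the policy contract (teacher-forced log-probabilities +
  stepwise sampling) is where such a cell would plug in.
* The NumPy implementation is single-threaded and sized for corpora of
  10³–10⁴ molecules; ChEMBL-scale pretraining is out of scope.
* No charge/stereo standardization beyond backend canonicalization; no
  applicability-domain or calibration analysis for the predictor.
* `vote_fraction` and `mean_probability` aggregation coexist without a
  ruling on which is preferable; downstream thresholds (0.75 cutoff)
  interact differently with the quantized mode.
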