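# cchr — cross-modal contrastive hashing retrieval

`cchr` implements cross-modal hashing retrieval between two synchronized
embedding streams — infrared sleep-video clips and EEG clips of the same
30-second epochs — so that a query in one modality retrieves the most
relevant clips of the other by Hamming distance over short binary codes.
It is aimed at researchers studying sleep monitoring pipelines in which a
cheap, home-deployable sensor (an IR camera) must be linked to the
clinical gold standard (PSG/EEG), and more generally at anyone who needs
a compact, reproducible reference implementation of contrastive hashing
with hard-negative mining.

## Method

Two frozen modality encoders are assumed to produce paired embeddings
`v_i, e_i ∈ R^D` (default D = 512) with a shared sleep-stage label
`y_i ∈ {W, N1, N2, N3, R}`. Two independent hashing networks
`f_v, f_e` (three fully connected layers, ReLU/ReLU/tanh, batch norm
before the output layer) map embeddings to continuous codes in
`(−1, 1)^L`. Training minimizes

```
L = Lc + λ1·Lq + λ2·Lbb
```

* **Contrastive loss** `Lc`: with similarity `S(a,b) = exp(cos(a,b)/τ)`,
  each anchor pair k contributes two hinge terms
  `[α − S(f_v(v_k), f_e(e_k)) + S(f_v(v_k), f_e(e_m))]_+` and
  `[α − S(f_v(v_k), f_e(e_k)) + S(f_v(v_n), f_e(e_k))]_+`, where m and n
  are the in-batch *hardest negatives* (the most similar non-matching
  rows of the other modality). Defaults: α = 0.25, τ = 1.
* **Quantization loss** `Lq = ‖B − F_v‖²_F + ‖B − F_e‖²_F` pulls the
  continuous codes toward the joint binary target
  `B = sign(½(F_v + F_e))` (λ1 = 0.001).
* **Bit-balance loss** `Lbb` penalizes squared per-bit column sums so
  every bit fires +1/−1 with equal chance (λ2 = 0.01).

After training, every gallery clip gets one joint binary code `B_i`,
stored bit-packed in a persistent code bank; a query is encoded by its
own modality's network, binarized by sign, and the gallery is ranked by
popcount Hamming distance. Quality is measured by MAP@N (mean average
precision at cut-off N; same-stage labels define relevance).

Everything is plain numpy: the networks, batch norm, the analytic
gradients of all three losses, and the Adam optimizer are implemented in
this package and verified against finite differences.

## Worked example

```python
from cchr.training import desk_scale_configs, run_experiment

syn, spec, train_cfg, eval_cfg = desk_scale_configs(seed=1)
res = run_experiment(syn, spec, train_cfg, eval_cfg)
print(f"MAP@100 video→EEG: {res.map_video_to_eeg:.4f}")
print(f"MAP@100 EEG→video: {res.map_eeg_to_video:.4f}")
```

prints

```
MAP@100 video→EEG: 0.9574
MAP@100 EEG→video: 0.9024
```

This generates 3,000 synthetic paired clips (five separable sleep-stage
clusters, two noisy linear views of a shared latent), trains 32-bit
hashing networks for 30 epochs at batch 64, builds the joint code bank
over the 2,700-clip gallery, and evaluates both retrieval directions
over 300 held-out queries. MAP@100 in the 0.85–0.97 range (the spread
across seeds) means that most of each query's top-100 list shares its
sleep stage — far above the ≈ 0.23 chance level of a shuffled gallery.

The same pipeline is scriptable stage by stage:

```bash
cchr simulate --out data/
cchr train --dataset data/ --out model/
cchr build-bank --checkpoint model/checkpoint.npz --dataset data/ --out bank.cchb
cchr retrieve --checkpoint model/checkpoint.npz --bank bank.cchb \
     --dataset data/ --direction video2eeg --top-k 1000 --out ranks.tsv
cchr evaluate --checkpoint model/checkpoint.npz --bank bank.cchb \
     --dataset data/ --direction video2eeg --cutoff 1000 --out metrics.json
```

plus `cchr ablate` (loss-term ablation grids) and `cchr sweep`
(one-at-a-time λ1/λ2/α sensitivity sweeps). Every command accepts a
YAML/JSON config and writes a manifest sufficient to reproduce its
outputs bit-for-bit.

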