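"""Train the three-classifier ensemble on a small synthetic dataset and
predict crosstalk for held-out pairs.

The generator plants the trends reported for real crosstalk pairs (spatial
proximity, inflated attention, shifted embeddings); training recovers them
and the weighted ensemble P = 0.65 P_seq + 0.35 (0.65 P_graph + 0.35 P_site)
scores each pair, calling crosstalk at P >= 0.15.
"""

from ptmct import SyntheticConfig, generate_dataset, predict_dataset, \
    train_all
from ptmct.graph_model import GraphTrainConfig
from ptmct.seq_model import SeqTrainConfig

config = SyntheticConfig(n_proteins=6, n_sites=8, n_positive=4,
                         n_negative=8, max_positive_sites=4,
                         length_min=30, length_max=40, seed=11)
dataset, provider, _ = generate_dataset(config)

bundle = train_all(
    dataset, provider,
    seq_config=SeqTrainConfig(learning_rate=1e-3, max_epochs=5, seed=11),
    graph_config=GraphTrainConfig(learning_rate=1e-3, max_epochs=10,
                                  seed=11),
    site_seed=11)

results = predict_dataset(bundle, dataset)
print("protein  pos_a pos_b  p_seq  p_graph p_site p_final call        label")
for r, pair in list(zip(results, dataset.pairs))[:8]:
    print(f"{r.protein_id:8s} {r.pos_a:5d} {r.pos_b:5d} "
          f"{r.p_seq:6.3f} {r.p_graph:7.3f} {r.p_site:6.3f} "
          f"{r.p_final:7.3f} {r.call:12s}{pair.label}")
# p_final is the convex combination of the three classifier probabilities;
# pairs at or above the 0.15 cutoff are called crosstalk. The cutoff is
# tuned for heavily imbalanced real data, so on this small balanced sample
# most pairs clear it — the separation shows in the scores: planted
# positives rank clearly above the negatives.
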