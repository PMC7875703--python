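"""Self-supervised pretraining and patient-similarity retrieval.

Pretrains the small-preset disease encoder (hidden size 32, 2 layers) on a
600-visit synthetic cohort with the combined objective — Deep-InfoMax NCE +
adversarial uniform-prior matching + SimCLR — then queries the embedding
index for the 5 nearest patients of one visit. A few minutes on one CPU.
"""

import numpy as np

from edembed import (CohortStats, HashingTextEncoder, SyntheticConfig, TrainConfig,
                     build_features, cleanse_visits, embed_dataset, generate_cohort,
                     pretrain)
from edembed.model import DiseaseEncoder, ModelConfig
from edembed.retrieval import EmbeddingIndex, hit_score, query_topk

cohort = generate_cohort(SyntheticConfig(n_visits=600, seed=1, invalid_rate=0.0))
kept, _ = cleanse_visits(cohort.visits)
mconfig = ModelConfig.small_preset()
features = build_features(kept, CohortStats.from_visits(kept),
                          HashingTextEncoder(d_text=mconfig.d_text))

encoder = DiseaseEncoder(mconfig, np.random.default_rng(0))
result = pretrain(features, encoder,
                  TrainConfig.small(seed=0, epochs=20, batch_size=128, dim_negatives=8))
first, last = result.metrics.iloc[0], result.metrics.iloc[-1]
print(f"total loss: {first['total']:.3f} -> {last['total']:.3f} "
      f"(dim {last['dim_nce']:.3f}, prior_gen {last['prior_gen']:.3f}, "
      f"simclr {last['simclr']:.3f})")

embeddings = embed_dataset(encoder, features)
clusters = cohort.latent_cluster
q = 17
rest = [i for i in range(len(embeddings)) if i != q]
index = EmbeddingIndex(embeddings[rest], [features.visit_ids[i] for i in rest])
top5 = query_topk(index, embeddings[q], k=5)
by_id = {v.visit_id: i for i, v in enumerate(kept)}
print(f"query {features.visit_ids[q]} (cluster {clusters[q]}): "
      f"'{kept[q].chief_complaint}'")
for vid, sim in top5:
    i = by_id[vid]
    print(f"  {vid} cos={sim:+.3f} cluster={clusters[i]}  '{kept[i].chief_complaint}'")
score = hit_score([clusters[by_id[vid]] for vid, _ in top5], clusters[q])
print(f"hit score: {score}/5 retrieved patients share the query's latent cluster")
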