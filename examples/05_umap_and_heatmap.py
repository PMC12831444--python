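"""Project learned features to 2-D and paint a held-out slide by predicted class.

Mirrors the two standard qualitative analyses: a UMAP scatter of backbone
embeddings coloured by tissue label, and a slide-level heatmap where each
tissue tile takes its predicted class colour (background stays neutral).
"""

import numpy as np
from sklearn.metrics import silhouette_score

from spcl.evaluation import embed_and_project, predict_wsi_heatmap
from spcl.pipeline import run_desk_experiment

res = run_desk_experiment(seed=1)
ds = res["dataset"]["test"]

coords = embed_and_project(res["result"], ds["X"], seed=0)
print(f"UMAP coordinates: {coords.shape};"
      f" silhouette by tissue label {silhouette_score(coords, ds['y']):.3f}")
# positive silhouette = same-class patches cluster in the embedding

slide = res["slides"][res["split"]["test"][0]]
heatmap, grid, manifest = predict_wsi_heatmap(res["classifier"], slide.image,
                                              tile_size=32)
predicted = grid[grid >= 0]
print(f"heatmap {heatmap.shape}: {len(manifest)} tissue tiles coloured, "
      f"{np.sum(grid < 0)} background cells neutral")
print("predicted class frequencies:",
      {int(c): int(n) for c, n in zip(*np.unique(predicted, return_counts=True))})
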