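# macrotraj

Classification of macrophage polarization subtypes (M0 / M1 / M2) from raw
single-cell migration trajectories.

Macrophages switch between a naive state (M0), a classically activated
pro-inflammatory state (M1, induced e.g. by LPS) and an alternatively
activated pro-reparatory state (M2, induced e.g. by IL-4). In time-lapse
cultures the three subtypes show distinct migratory signatures: circular M0
cells spin in place near their start, protruded M1 cells make large jumps
while wandering around their origin, and elongated M2 cells move
persistently in one direction. `macrotraj` turns centroid track tables from
such recordings into a subtype call, and ships a stochastic motility
simulator so the whole pipeline can be exercised and benchmarked without
any imaging data.

The pipeline, in the order it runs:

1. **Track ingestion** — CSV tables (`cell_id, frame, t, x, y, label`),
   keeping only cells tracked from the first frame to the last
   (default 37 frames at 5 min/frame).
2. **Trajectory metrics** — for each track of points
   $p_0,\dots,p_{T-1}$: path length $\sum_k \lVert p_{k+1}-p_k\rVert$,
   net displacement $\lVert p_{T-1}-p_0\rVert$, convex hull perimeter and
   area, and the diameter $\max_{i,j}\lVert p_i-p_j\rVert$ (maximum
   pairwise distance).
3. **Symmetry augmentation** — each labeled track is expanded by the eight
   axis isometries $(x,y)\mapsto(y,x),(-x,y),(-x,-y),(x,-y),(-y,x),
   (-y,-x),(y,-x)$ plus the identity; all trajectory metrics are invariant
   under every one of them.
4. **Feature construction** — each track becomes the fixed-length vector
   $[x_0..x_{T-1},\,y_0..y_{T-1},\,\text{path length},\,\text{displacement}]$
   (length $2T+2 = 76$), centered on its start point, with a one-hot label;
   records are shuffled and split 80/20 (560 records → 448 / 112).
5. **Classifier** — a dense softmax network with eight hidden
   relu layers of 10, 20, 32, 64, 64, 32, 20, 10 units and a 3-unit softmax
   output, trained with categorical cross-entropy under RMSprop
   (learning rate $10^{-3}$) for 100 epochs.
6. **Evaluation** — a row-normalized percent confusion matrix with true
   morphology clusters (Cluster C/P/E, the circular / protruded / elongated
   ground-truth proxies for M0/M1/M2) in rows and predicted subtypes in
   columns; the diagonal is the per-class accuracy.

## Worked example

```python
import macrotraj as mt

tracks = mt.generate_labeled_dataset(mt.SimConfig(n_per_class=70, seed=1))
complete = mt.filter_complete_tracks(tracks)
print(f"{len(complete)} complete tracks")

metrics = mt.summarize_metrics(complete)
print(metrics.groupby("label")[["hull_perimeter", "hull_area",
                                "max_pairwise_distance"]].mean().round(1))

records = mt.build_dataset(mt.augment_trackset(complete))
split = mt.shuffle_split(records, 0.8, seed=1)
print(f"{len(records)} augmented records -> "
      f"{len(split.train)} train / {len(split.validation)} validation")

model = mt.build_model(mt.ModelConfig(epochs=100, seed=1), 76)
mt.train(model, split.train, split.validation)
cm, acc = mt.evaluate(model, split.validation)
print(f"overall validation accuracy: {acc:.3f}")
print(cm.percent.round(1))
```

prints

```
210 complete tracks
       hull_perimeter  hull_area  max_pairwise_distance
label
M0               28.4       60.4                    9.7
M1               61.8      231.6                   24.3
M2               84.0      305.1                   36.8
1680 augmented records -> 1344 train / 336 validation
overall validation accuracy: 0.991
[[100.    0.    0. ]
 [  0.   97.5   2.5]
 [  0.    0.  100. ]]
```

The metric table shows the class signatures the simulator is built to
reproduce: hull perimeter and area ordered M2 > M1 > M0, and a maximum
pairwise distance that cleanly separates M1 from M0 while M1 and M2 remain
similar. The confusion matrix (rows: true Cluster C/P/E; columns: predicted
M0/M1/M2) shows the network recovering all three motility classes from the
coordinate time series alone — note that because the split happens after
augmentation, symmetry variants of one cell can appear on both sides, so
these validation numbers are optimistic about truly unseen cells (use
`group_by_origin=True` in `shuffle_split` for a leakage-free split).

The same analysis is available as a subcommand CLI
(`macrotraj simulate | metrics | augment | build-dataset | train | predict |
evaluate | report | run`); `macrotraj run --seed 1 --out-dir run/` executes
the whole pipeline and writes every intermediate CSV, the figures
(trajectory overlays, time-gradient paths, metric box plots, training
curves, confusion heatmap) and the resolved YAML config into the run
directory.

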