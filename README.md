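# tillerscan

Automatic counting of wheat tillers in field-grown crop rows scanned with a
terrestrial laser scanner (TLS).

Tiller number per unit area is a primary yield component of wheat and is
conventionally obtained by manual counting in sample row sections — slow,
laborious and error-prone. `tillerscan` implements a two-stage point-cloud
method that counts tillers directly in the 3D scan of a single crop row:

1. **Adaptive layering (AL)** — the row is sliced into *n* equal-height
   layers (layer 1 at the canopy top). Each adjacent layer pair (leaf layer
   *i*, stem layer *i+1*) is projected onto the ground plane and binned
   along the row axis X. Because overlapping leaves project to a nearly
   continuous band while stems are interrupted by the interspaces between
   densely aggregated plant groups ("wheat clusters"), bins containing
   stem-layer points ("mixed parts") separated by leaf-only gaps mark the
   clusters. The pair maximising the cluster count T<sub>i−(i−1)</sub>
   defines the leaf/stem separation layer and its mixed runs become cluster
   segments.
2. **Hierarchical clustering (HC)** — within each cluster segment the
   stem-zone points are agglomeratively clustered under Euclidean distance
   d<sub>ij</sub> = √Σ(x<sub>ik</sub>−x<sub>jk</sub>)², merging while the
   minimum inter-class distance is ≤ *d* (default **d = 2 cm**, the assumed
   minimum spacing of field-grown tillers). The surviving classes are the
   tillers; the row total is T<sub>row</sub> = Σ per-cluster counts.

The row count scales to a plot-level density via

```
T_plot = T_row · r / S        [tillers / m²]
```

with *r* rows per plot and plot area *S* (m²). Agreement with reference
counts is scored with R², RMSE and RRMSE.

Because field scans with paired manual counts are rarely public, the
package bundles a synthetic TLS row generator with exact per-point ground
truth (cluster id, tiller id, stem/leaf/noise kind), so every stage — and
the full pipeline — is testable end to end.

## Worked example

```python
import tillerscan as ts

# a 1 m synthetic row: ~6 wheat clusters, 2-5 tillers each, bridged canopy
truth = ts.generate_row(ts.RowScenario(seed=1))
print(len(truth.cloud), truth.true_cluster_count, truth.true_tiller_count)

result = ts.count_row(truth.cloud)                      # AL -> HC
result.T_plot = ts.to_plot_density(result.T_row, ts.PlotSpec(r=26, S=30.0))
print(result.separation_layer, result.T_row, round(result.T_plot, 2))

print(ts.sweep_d(truth.cloud, [0.005, 0.015, 0.02, 0.025, 0.03]))
```

prints

```
22691 6 16
8 16 13.87
       d  T_row
0  0.005     27
1  0.015     16
2  0.020     16
3  0.025     16
4  0.030     15
```

The generated row holds 22 691 points forming 6 clusters with 16 tillers in
total. The AL step picks layer 8 (of 10) as the leaf/stem separation; HC
recovers all 16 tillers exactly (T_row = 16), i.e. 13.87 tillers/m² for a
26-row, 30 m² plot. The threshold sweep shows the expected behaviour: a
0.5 cm cut splits single tillers into several classes (27), while a 3 cm
cut starts merging neighbouring tillers (15); counts are non-increasing
in *d*.

The same pipeline is available from the shell:

```bash
tillerscan simulate --seed 1 --out row.ply
tillerscan count --input row.ply --plot-rows 26 --plot-area 30
tillerscan sweep --input row.ply --d 0.005,0.015,0.02,0.025,0.03
tillerscan evaluate --pairs pairs.csv
```

Row clouds are accepted as PLY (ascii / binary little-endian), LAS
(point formats 0–3) or XYZ CSV, in m/cm/mm; see `tillerscan --help` and the
config example in `tillerscan.cli`.

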