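"""Run the whole pipeline on a synthetic corpus and interpret the clusters.

Synthesis → segmentation → spectrograms → autoencoder → embeddings →
PCA/UMAP → K-means → decoded prototype spectrograms → diel histograms.
Prints the per-stage summary and, per cluster, the prototype's dominant
frequency band and the hours where the cluster's recordings concentrate.
"""

import tempfile

import h5py
import numpy as np
import pandas as pd

from soundscape_ae import run_pipeline
from soundscape_ae.pipeline import ClusterStage, PipelineConfig, ProjectStage, SynthStage
from soundscape_ae.cae import AutoencoderConfig

config = PipelineConfig(
    seed=0,
    synth=SynthStage(n_recorders=1, recordings_per_hour=1),  # 24 one-minute files
    cae=AutoencoderConfig(epochs=1, batch_segments=10),
    project=ProjectStage(methods=("pca", "umap"), n_components=8),
    cluster=ClusterStage(space="umap", k=3),
)

run_dir = tempfile.mkdtemp(prefix="run_")
result = run_pipeline(config, run_dir)
for stage, entry in result.summary.items():
    print(f"{stage:10s} {result.stage_status[stage]:9s} {entry['counts']}")

with h5py.File(f"{run_dir}/prototypes.h5") as f:
    protos = f["prototypes"][:]
diel = pd.read_csv(f"{run_dir}/diel.csv")
bin_hz = 22_050 / 1_028
for j, proto in enumerate(protos):
    peak = int(np.argmax(proto.mean(axis=1)))
    hours = diel[diel["cluster"] == j]
    top = hours.sort_values("count", ascending=False).head(3)["hour"].tolist()
    print(f"cluster {j}: dominant band ~{peak * bin_hz:,.0f} Hz, busiest hours {top}")
# The prototypes separate the planted frequency niches; the busiest hours
# track each component's scheduled activity window.
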