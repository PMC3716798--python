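"""Readers and writers for the formats the tool touches.

FASTA input goes through Biopython.  Output formats are all small text
formats: MEME minimal motif blocks for PWMs, GFF3 for predicted or true
sites (1-based inclusive coordinates), JSON manifests for candidate
model sets and YAML for dataset specifications.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import CandidateModelSet
from .models import MotifModel, SitePredictionSet, score_model
from .synthetic import DatasetSpec, PlantedDataset


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; wrapped lines and lower case handled upstream."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_meme_motifs(path, models: dict[int, MotifModel] | list[MotifModel]) -> None:
    """MEME minimal motif format: one letter-probability block per model."""
    if isinstance(models, dict):
        models = [models[w] for w in sorted(models)]
    first = models[0]
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        " ".join(
            f"{b} {f:.4f}" for b, f in zip("ACGT", first.theta0)
        ),
        "",
    ]
    for model in models:
        lines.append(f"MOTIF width{model.width} {model.consensus()}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {model.width} "
            f"nsites= 20 E= 0"
        )
        for row in model.theta1:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gff3(
    path,
    predictions: SitePredictionSet,
    seq_ids: list[str],
    source: str = "mcoin",
    feature: str = "TF_binding_site",
) -> None:
    """Predicted sites as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for k, site in enumerate(predictions.sites):
        start = site.start + 1
        end = site.start + predictions.width
        attrs = f"ID=site{k};posterior={site.posterior:.4f}"
        lines.append(
            "\t".join(
                [
                    seq_ids[site.seq_index],
                    source,
                    feature,
                    str(start),
                    str(end),
                    f"{site.score:.4f}",
                    site.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_gff3(path, dataset: PlantedDataset, seq_ids: list[str]) -> None:
    lines = ["##gff-version 3"]
    for k, (i, start) in enumerate(dataset.true_sites):
        lines.append(
            "\t".join(
                [
                    seq_ids[i],
                    "planted",
                    "TF_binding_site",
                    str(start + 1),
                    str(start + dataset.width),
                    ".",
                    "+",
                    ".",
                    f"ID=true{k}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset_spec(path, spec: DatasetSpec) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "n_sequences": spec.n_sequences,
                "seq_length": spec.seq_length,
                "motif_width": spec.motif_width,
                "target_ic": spec.target_ic,
                "background_composition": list(spec.background_composition),
                "seed": spec.seed,
            }
        )
    )


def read_dataset_spec(path) -> DatasetSpec:
    data = yaml.safe_load(Path(path).read_text())
    if "background_composition" in data and data["background_composition"] is not None:
        data["background_composition"] = tuple(data["background_composition"])
    return DatasetSpec(**data)


def save_candidates(path, candidates: CandidateModelSet) -> None:
    """JSON manifest of a candidate model set (parameters + selection statistics)."""
    payload = {
        "w_min": candidates.w_min,
        "w_max": candidates.w_max,
        "models": {
            str(w): {
                "theta1": np.asarray(candidates[w].model.theta1).tolist(),
                "theta0": np.asarray(candidates[w].model.theta0).tolist(),
                "lam": candidates[w].model.lam,
                "bic": candidates[w].bic,
                "log_likelihood": candidates[w].log_likelihood,
                "ic_per_col": candidates[w].ic_per_col,
                "n_pred": candidates[w].n_pred,
            }
            for w in candidates.widths
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def load_candidates(path, sequences: list[str]) -> CandidateModelSet:
    """Rebuild a candidate set from a manifest, rescoring against the sequences."""
    data = json.loads(Path(path).read_text())
    models = {}
    for w_str, entry in data["models"].items():
        model = MotifModel(
            theta1=np.asarray(entry["theta1"], dtype=float),
            theta0=np.asarray(entry["theta0"], dtype=float),
            lam=float(entry["lam"]),
        )
        models[int(w_str)] = score_model(model, sequences)
    return CandidateModelSet(models=models, w_min=data["w_min"], w_max=data["w_max"])
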