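"""Plain-text readers/writers for every artifact the pipeline exchanges.

Datasets are tab-delimited genes x features tables plus a feature
manifest; labels, signatures and predictions are small TSVs; parameters
travel as JSON sidecars.  Everything round-trips bit-identically via
``repr`` float formatting.
"""

from __future__ import annotations

import dataclasses
import json
import os

import pandas as pd

from dls.classify import Prediction
from dls.ontology import TrainingSet
from dls.preprocess import ConditionPair, ExpressionDataset, RawExperimentSet
from dls.signatures import ExpressionSignature, SignatureModel, SignatureParams


# ---------------------------------------------------------------------------
# datasets


def write_dataset(dataset: ExpressionDataset, prefix: str) -> None:
    fids = dataset.feature_ids
    pd.DataFrame(dataset.x_lr, index=dataset.gene_ids, columns=fids).to_csv(
        f"{prefix}.lr.tsv", sep="\t", float_format="%.17g"
    )
    pd.DataFrame(dataset.x_fdr, index=dataset.gene_ids, columns=fids).to_csv(
        f"{prefix}.fdr.tsv", sep="\t", float_format="%.17g"
    )
    with open(f"{prefix}.features.tsv", "w") as fh:
        fh.write("feature_id\texperiment\tcontrol\ttest\n")
        for f in dataset.features:
            fh.write(f"{f.feature_id}\t{f.experiment_id}\t{f.control}\t{f.test}\n")


def read_dataset(prefix: str) -> ExpressionDataset:
    lr = pd.read_csv(f"{prefix}.lr.tsv", sep="\t", index_col=0, float_precision="round_trip")
    fdr = pd.read_csv(f"{prefix}.fdr.tsv", sep="\t", index_col=0, float_precision="round_trip")
    manifest = pd.read_csv(f"{prefix}.features.tsv", sep="\t", dtype=str)
    features = [
        ConditionPair(row["experiment"], row["control"], row["test"])
        for _, row in manifest.iterrows()
    ]
    return ExpressionDataset(
        gene_ids=[str(g) for g in lr.index],
        features=features,
        x_lr=lr.to_numpy(),
        x_fdr=fdr.to_numpy(),
    )


# ---------------------------------------------------------------------------
# raw experiments


def read_experiment(intensity_path: str, conditions_path: str, experiment_id: str) -> RawExperimentSet:
    """Wide intensity table (rows = genes, header = sample ids) + sample->condition sidecar."""
    table = pd.read_csv(intensity_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t", header=None, names=["sample", "condition"], dtype=str)
    return RawExperimentSet(
        experiment_id=experiment_id,
        gene_ids=[str(g) for g in table.index],
        sample_ids=[str(s) for s in table.columns],
        intensities=table.to_numpy(dtype=float),
        sample_condition=dict(zip(cond["sample"], cond["condition"])),
    )


def read_experiments_dir(directory: str) -> list[RawExperimentSet]:
    """Every ``<id>.tsv`` with a matching ``<id>.conditions.tsv``."""
    out = []
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".tsv") or name.endswith(".conditions.tsv"):
            continue
        exp_id = name[: -len(".tsv")]
        sidecar = os.path.join(directory, f"{exp_id}.conditions.tsv")
        if not os.path.exists(sidecar):
            continue
        out.append(read_experiment(os.path.join(directory, name), sidecar, exp_id))
    if not out:
        raise FileNotFoundError(f"no experiment tables found in {directory!r}")
    return out


def read_pairs(path: str) -> list[ConditionPair]:
    """Manual pair list: TSV with experiment, control, test columns."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ConditionPair(row["experiment"], row["control"], row["test"])
        for _, row in table.iterrows()
    ]


# ---------------------------------------------------------------------------
# labels


def write_labels(training: TrainingSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlabel\tterm\n")
        for g in sorted(training.positives):
            fh.write(f"{g}\tpositive\t{training.process_term}\n")
        for g in sorted(training.negatives):
            fh.write(f"{g}\tnegative\t{training.process_term}\n")


def read_labels(path: str) -> TrainingSet:
    table = pd.read_csv(path, sep="\t", dtype=str)
    term = table["term"].iloc[0] if "term" in table and len(table) else "unknown"
    pos = set(table.loc[table["label"] == "positive", "gene"])
    neg = set(table.loc[table["label"] == "negative", "gene"])
    return TrainingSet(process_term=term, positives=pos, negatives=neg)


# ---------------------------------------------------------------------------
# signatures


def write_signatures(model: SignatureModel, prefix: str) -> None:
    with open(f"{prefix}.signatures.tsv", "w") as fh:
        fh.write("gene\tess\tc_pos\tc_neg\tvalid\tfeatures\n")
        for s in model.signatures:
            feats = ";".join(str(f) for f in s.features)
            fh.write(f"{s.gene}\t{s.ess!r}\t{s.c_pos!r}\t{s.c_neg!r}\t{int(s.valid)}\t{feats}\n")
    with open(f"{prefix}.params.json", "w") as fh:
        json.dump(dataclasses.asdict(model.params), fh, indent=2)


def read_signatures(prefix: str, training: TrainingSet) -> SignatureModel:
    with open(f"{prefix}.params.json") as fh:
        params = SignatureParams(**json.load(fh))
    signatures = []
    table = pd.read_csv(f"{prefix}.signatures.tsv", sep="\t", dtype=str)
    for _, row in table.iterrows():
        feats = tuple(int(f) for f in row["features"].split(";")) if isinstance(row["features"], str) and row["features"] else ()
        signatures.append(
            ExpressionSignature(
                gene=row["gene"],
                features=feats,
                ess=float(row["ess"]),
                c_pos=float(row["c_pos"]),
                c_neg=float(row["c_neg"]),
                valid=bool(int(row["valid"])),
            )
        )
    return SignatureModel(signatures=signatures, params=params, training=training)


# ---------------------------------------------------------------------------
# predictions


def write_predictions(predictions: list[Prediction], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsignature_gene\tL\tconfidence\n")
        for p in predictions:
            fh.write(f"{p.gene}\t{p.signature_gene}\t{p.coexpression!r}\t{p.confidence!r}\n")


def read_predictions(path: str) -> list[Prediction]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Prediction(
            gene=row["gene"],
            signature_gene=row["signature_gene"],
            coexpression=float(row["L"]),
            confidence=float(row["confidence"]),
        )
        for _, row in table.iterrows()
    ]


def read_gene_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
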