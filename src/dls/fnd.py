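"""Iterative false-negative discovery (FND).

Negative training labels are noisy: a gene without an annotation may
still belong to the process.  Each FND iteration (1) trains with the
bootstrap discard enabled and keeps only the negatives discarded by at
least one valid signature as candidates, (2) keeps the candidates the
trained model predicts positive, and (3) searches a signature for each
survivor (bootstrap off); a candidate is confirmed when its score clears
the validity threshold and its positive co-expression component is at
least the average over the positive class's valid signatures.  Confirmed
genes move to the positive class for the next iteration, until a
fixpoint or the iteration cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from dls.classify import fit_densities, predict_genes
from dls.ontology import TrainingSet
from dls.preprocess import ExpressionDataset
from dls.signatures import SignatureParams, signfs, train

logger = logging.getLogger(__name__)


@dataclass
class FNDState:
    iteration: int = 0
    candidates: list[str] = field(default_factory=list)
    confirmed: list[str] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)


def fnd_iteration(
    state: FNDState,
    dataset: ExpressionDataset,
    training: TrainingSet,
    params: SignatureParams,
    conf_threshold: float = 0.9,
    bandwidth_spec: float | str = "silverman",
) -> tuple[FNDState, TrainingSet]:
    """One bound-and-refine pass; returns the updated state and training set."""
    if len(training.positives) < 2:
        raise ValueError("FND needs at least 2 positive genes")

    record: dict = {"iteration": state.iteration + 1}

    # Step 1: bootstrap training bounds the candidates to discarded negatives.
    boot_params = replace(params, bootstrap=True)
    model = train(dataset, training, boot_params)
    valid = model.valid_signatures
    discarded: set[str] = set()
    for sig in valid:
        discarded |= set(sig.discarded_negatives)
    theta = sorted(set(training.negatives) & discarded)
    record["after_step1"] = list(theta)

    # Step 2: keep candidates the trained model predicts positive.  The
    # candidates themselves are left out of the negative density samples —
    # the model was trained with them discarded, and keeping them would
    # let suspected mislabels vouch for their own negative status.
    if theta and valid:
        density_training = TrainingSet(
            process_term=training.process_term,
            positives=set(training.positives),
            negatives=set(training.negatives) - set(theta),
            negative_terms=set(training.negative_terms),
        )
        fit_densities(model, dataset, density_training, bandwidth_spec)
        preds = predict_genes(model, dataset, theta, conf_threshold)
        predicted = {p.gene for p in preds}
        theta = sorted(set(theta) & predicted)
    else:
        theta = []
    record["after_step2"] = list(theta)

    # Step 3: a candidate is confirmed when its own signature is valid and
    # it is at least as connected as an average positive gene.
    plain_params = replace(params, bootstrap=False)
    mean_c_pos = float(np.mean([s.c_pos for s in valid])) if valid else float("inf")
    record["mean_c_pos"] = mean_c_pos
    confirmed: list[str] = []
    record["candidate_scores"] = {}
    for g in theta:
        sig = signfs(g, dataset, training, plain_params)
        record["candidate_scores"][g] = {"ess": sig.ess, "c_pos": sig.c_pos}
        if sig.ess > params.tau_valid and sig.c_pos >= mean_c_pos:
            confirmed.append(g)
    record["confirmed"] = list(confirmed)

    new_training = training
    if confirmed:
        new_training = TrainingSet(
            process_term=training.process_term,
            positives=training.positives | set(confirmed),
            negatives=training.negatives - set(confirmed),
            negative_terms=set(training.negative_terms),
        )

    new_state = FNDState(
        iteration=state.iteration + 1,
        candidates=theta,
        confirmed=state.confirmed + confirmed,
        history=state.history + [record],
    )
    return new_state, new_training


def run_fnd(
    dataset: ExpressionDataset,
    training: TrainingSet,
    params: SignatureParams,
    max_iter: int = 10,
    conf_threshold: float = 0.9,
    bandwidth_spec: float | str = "silverman",
    promote: bool = True,
) -> tuple[FNDState, TrainingSet]:
    """Iterate :func:`fnd_iteration` until no new confirmations or ``max_iter``.

    With ``promote`` (the default) confirmed genes end up in the positive
    class of the refined set; otherwise they are only removed from the
    negative class.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    training = training.restricted_to(dataset.gene_ids)
    state = FNDState(candidates=sorted(training.negatives))
    current = training
    for _ in range(max_iter):
        prev_confirmed = len(state.confirmed)
        state, current = fnd_iteration(
            state, dataset, current, params, conf_threshold, bandwidth_spec
        )
        if len(state.confirmed) == prev_confirmed:
            break
    if not promote and state.confirmed:
        current = TrainingSet(
            process_term=training.process_term,
            positives=set(training.positives),
            negatives=set(training.negatives) - set(state.confirmed),
            negative_terms=set(training.negative_terms),
        )
    logger.info("FND confirmed %d false negatives in %d iterations",
                len(state.confirmed), state.iteration)
    return state, current
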