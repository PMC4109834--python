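"""End-to-end training and weighted-residual prediction.

Training composes the pipeline stages: extract layout features from each
labeled figure, standardize them, learn one incoherent dictionary per
class, compute the per-feature residual profile of the training set, and
fit the feature weights by linear programming.  Prediction assigns a
sample to the class whose dictionary reconstructs it best under the
learned weights:

    j_hat = argmin_j  sum_k omega_k (x_k - (D^(j) a_hat_j)_k)^2 .

By default the model works at the five top-level taxonomy classes; leaf
(eight-class) granularity is available through ``granularity="leaf"``.

Whole figures are classified through :func:`classify_figure`: the image
is first split into panels, each panel is classified independently, and a
figure whose panels span two or more distinct top-level categories is
reported as ``"mix"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from figcat import panels as panels_mod
from figcat.layout_features import DEFAULT_TAU, FEATURE_DIM, FeatureVector, MIN_RUN, extract_features
from figcat.sparse_model import (
    DEFAULT_ETA,
    DEFAULT_ITERS,
    DEFAULT_LAMBDA,
    Dictionary,
    lasso_matrix,
    learn_class_dictionaries,
    residual_profile,
)
from figcat.taxonomy import top_level
from figcat.textmap import TextRegion, detect_text_regions
from figcat.weighting import fit_weights

STD_FLOOR = 1e-8


@dataclass
class ClassModel:
    """Trained model: per-class dictionaries, weights, standardization."""

    classes: list[str]
    dictionaries: dict[str, Dictionary]
    omega: np.ndarray
    epsilon: float
    lam: float
    eta: float
    mean: np.ndarray
    std: np.ndarray
    config: dict = field(default_factory=dict)

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.std

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "atoms": {lab: d.atoms.tolist() for lab, d in self.dictionaries.items()},
            "omega": self.omega.tolist(),
            "epsilon": self.epsilon,
            "lambda": self.lam,
            "eta": self.eta,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "config": self.config,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "ClassModel":
        return cls(
            classes=list(d["classes"]),
            dictionaries={
                lab: Dictionary(atoms=np.array(a), label=lab)
                for lab, a in d["atoms"].items()
            },
            omega=np.array(d["omega"]),
            epsilon=float(d["epsilon"]),
            lam=float(d["lambda"]),
            eta=float(d["eta"]),
            mean=np.array(d["mean"]),
            std=np.array(d["std"]),
            config=dict(d.get("config", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _figure_features(fig, tau: float, min_run: int) -> np.ndarray:
    return extract_features(fig.image, fig.regions, tau=tau, min_run=min_run).values


def train(
    figures,
    granularity: str = "top",
    m: int | None = None,
    lam: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
    iters: int = DEFAULT_ITERS,
    tau: float = DEFAULT_TAU,
    min_run: int = MIN_RUN,
    seed: int = 0,
) -> ClassModel:
    """Train a class model on labeled figures with ground-truth regions.

    ``figures`` is any sequence of objects carrying ``image``, ``regions``
    and ``label`` attributes (e.g. :class:`figcat.fixtures.SyntheticFigure`).
    Labels are mapped to the requested granularity; classes are taken from
    the data, each needing at least one sample.  The atom count defaults
    to ``min(smallest class size, 50)``.
    """
    if granularity not in ("top", "leaf"):
        raise ValueError("granularity must be 'top' or 'leaf'")
    feats, labels = [], []
    for fig in figures:
        x = _figure_features(fig, tau, min_run)
        if x.shape != (FEATURE_DIM,):
            raise ValueError(f"feature length {x.shape} != {FEATURE_DIM}")
        feats.append(x)
        labels.append(top_level(fig.label) if granularity == "top" else fig.label)
    if not feats:
        raise ValueError("empty training set")
    X = np.array(feats).T  # K x N
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("training needs at least 2 classes")

    mean = X.mean(axis=1)
    std = X.std(axis=1)
    std = np.where(std < STD_FLOOR, 1.0, std)
    Z = (X - mean[:, None]) / std[:, None]

    by_class = {c: Z[:, [i for i, l in enumerate(labels) if l == c]] for c in classes}
    if m is None:
        m = min(min(v.shape[1] for v in by_class.values()), 50)
    dicts = learn_class_dictionaries(by_class, m=m, lam=lam, eta=eta, iters=iters, seed=seed)
    dicts = {c: dicts[c] for c in classes}

    profile = residual_profile(Z, dicts, lam=lam)
    label_idx = np.array([classes.index(l) for l in labels])
    sol = fit_weights(profile, label_idx)

    return ClassModel(
        classes=classes,
        dictionaries=dicts,
        omega=sol.omega,
        epsilon=sol.epsilon,
        lam=lam,
        eta=eta,
        mean=mean,
        std=std,
        config={
            "granularity": granularity,
            "m": int(m),
            "iters": int(iters),
            "tau": float(tau),
            "min_run": int(min_run),
            "seed": int(seed),
        },
    )


def predict(x, model: ClassModel) -> tuple[str, np.ndarray]:
    """Classify one feature vector; returns (label, per-class scores).

    The score of class ``j`` is the omega-weighted squared residual of the
    standardized sample under that class's dictionary; the predicted label
    attains the minimum, ties broken toward the lowest class index.
    """
    if isinstance(x, FeatureVector):
        x = x.values
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape != model.mean.shape:
        raise ValueError(f"feature length {x.shape} != model dimension {model.mean.shape}")
    z = model.standardize(x)
    scores = np.empty(len(model.classes))
    for ci, lab in enumerate(model.classes):
        atoms = model.dictionaries[lab].atoms
        a = lasso_matrix(z[:, None], atoms, model.lam)[:, 0]
        r = z - atoms @ a
        scores[ci] = float(model.omega @ (r * r))
    return model.classes[int(np.argmin(scores))], scores


def _clip_regions_to_panel(
    regions: list[TextRegion], panel: panels_mod.PanelRegion
) -> list[TextRegion]:
    """Intersect regions with a panel and shift into panel coordinates."""
    out = []
    for r in regions:
        x0 = max(r.x0, panel.c0)
        x1 = min(r.x1, panel.c1)
        y0 = max(r.y0, panel.r0)
        y1 = min(r.y1, panel.r1)
        if x0 < x1 and y0 < y1:
            out.append(TextRegion(x0 - panel.c0, y0 - panel.r0, x1 - panel.c0, y1 - panel.r0, source=r.source))
    return out


def classify_figure(
    image: np.ndarray,
    model: ClassModel,
    regions: list[TextRegion] | None = None,
    detector=None,
) -> tuple[str, list[dict]]:
    """Classify a whole figure, panel by panel.

    The image is segmented into panels; each panel is classified
    independently on its own text regions (clipped ground truth when
    ``regions`` is supplied, otherwise the panel is binarized and run
    through ``detector``, defaulting to the baseline text detector).  A
    figure whose panels span at least two distinct top-level categories
    is labeled ``"mix"``; otherwise the common panel label is returned.

    Returns the figure label and a per-panel record (rectangle, label,
    scores).
    """
    image = np.asarray(image)
    found = panels_mod.segment(image)
    if not found:
        found = [panels_mod.PanelRegion(0, 0, image.shape[0], image.shape[1])]
    details = []
    for panel in found:
        crop = panel.crop(image)
        if regions is not None:
            panel_regions = _clip_regions_to_panel(regions, panel)
        else:
            det = detector or detect_text_regions
            panel_regions = det(panels_mod.binarize(crop))
        x = extract_features(
            crop,
            panel_regions,
            tau=model.config.get("tau", DEFAULT_TAU),
            min_run=model.config.get("min_run", MIN_RUN),
        )
        label, scores = predict(x, model)
        details.append(
            {
                "panel": (panel.r0, panel.c0, panel.r1, panel.c1),
                "label": label,
                "scores": scores.tolist(),
            }
        )
    tops = {top_level(d["label"]) for d in details}
    figure_label = "mix" if len(tops) > 1 else details[0]["label"]
    return figure_label, details
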