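import numpy as np
import pytest

from imnpheno.synth import SceneSpec, generate_static_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default mixed-class scene shared across tests (seeded)."""
    spec = SceneSpec(seed=7)
    channels, truth = generate_static_scene(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def sparse_imn_scene():
    """Noiseless, well-separated iMN-only field for exact morphometry."""
    spec = SceneSpec(
        seed=11, n_imn=10, n_non_neuron=0, n_dead=0, noise_sigma=0.0, min_separation_um=40.0
    )
    channels, truth = generate_static_scene(spec)
    return spec, channels, truth


def match_to_truth(row_centroid, truth, max_dist_px=15.0):
    """Nearest ground-truth cell to a detection centroid, or None."""
    best, best_d = None, np.inf
    for cell in truth.cells:
        d = np.hypot(row_centroid[0] - cell.centroid[0], row_centroid[1] - cell.centroid[1])
        if d < best_d:
            best, best_d = cell, d
    return best if best_d <= max_dist_px else None


def classification_scores(table, truth, max_dist_px=15.0):
    """Per-class precision/recall of a phenotyping table against truth."""
    out = {}
    for cls in ("iMN", "non_neuron", "dead"):
        tp = fp = 0
        sub = table[table["class"] == cls]
        for _, row in sub.iterrows():
            cell = match_to_truth((row.centroid_row, row.centroid_col), truth, max_dist_px)
            if cell is not None and cell.cell_class == cls:
                tp += 1
            else:
                fp += 1
        n_truth = len(truth.of_class(cls))
        out[cls] = (
            tp / max(1, tp + fp),
            tp / max(1, n_truth),
        )
    return out
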