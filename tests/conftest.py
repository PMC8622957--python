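import pytest

from scdsparse.preprocess import Beat
from scdsparse.synthetic import make_planted_sparse_set


@pytest.fixture
def small_dictionary():
    from scdsparse.sparse_core import init_dictionary

    return init_dictionary(4, 8, seed=1)


def planted_beat_cohort(
    labels,
    s=3,
    n_subjects=4,
    beats_per=25,
    n=32,
    m=48,
    seed=0,
    noise_sigma=0.0,
):
    """Beats whose values are s-sparse signals over one hidden random
    dictionary per class — a pipeline-free stand-in for segmented beats,
    used to exercise the classifier and cross-validation machinery."""
    beats = []
    for r, lab in enumerate(labels):
        ps = make_planted_sparse_set(
            n=n, m=m, M=n_subjects * beats_per, s=s,
            noise_sigma=noise_sigma, seed=seed + 13 * r,
        )
        for i in range(n_subjects):
            for t in range(i * beats_per, (i + 1) * beats_per):
                beats.append(
                    Beat(
                        values=ps.signals[:, t],
                        source_rr_samples=n,
                        class_label=lab,
                        subject_id=f"{lab}_s{i}",
                    )
                )
    return beats


def relabel(beats, label_of_subject):
    """Copy beats with subject-level labels reassigned."""
    return [
        Beat(
            values=b.values,
            source_rr_samples=b.source_rr_samples,
            class_label=label_of_subject[b.subject_id],
            subject_id=b.subject_id,
        )
        for b in beats
    ]
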