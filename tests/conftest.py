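import pytest

import mthap


@pytest.fixture(scope="session")
def reference():
    return mthap.build_reference(seed=1)


@pytest.fixture(scope="session")
def profiles():
    return mthap.builtin_profiles()


@pytest.fixture(scope="session")
def consensuses(reference, profiles):
    return {h: mthap.apply_profile(reference, p) for h, p in profiles.items()}


@pytest.fixture(scope="session")
def dloop_alignment(consensuses):
    """Reference-projected D-loop sequences, ten individuals per haplotype."""
    from mthap.defaults import D_LOOP_SPAN
    d0, d1 = D_LOOP_SPAN
    seqs, labels = [], []
    for hap in sorted(consensuses):
        cons = consensuses[hap]
        idx = cons.position_index()
        dloop = "".join(
            cons.sequence[idx[p]] if p in idx else "-"
            for p in range(d0, d1 + 1))
        for k in range(10):
            seqs.append(dloop)
            labels.append(f"{hap}{k}")
    return seqs, labels
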