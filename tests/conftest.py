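import pytest
from hypothesis import HealthCheck, settings

from icf_adl import Assessment, Cause, Domain, ItemResponse, load_catalog

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


def make_assessment(domain, scores, causes=None, relevant=None,
                    participant_id="P0001", report_mode="self"):
    """Build an assessment over the real catalog from parallel per-item lists.

    ``scores[i] is None`` together with ``relevant[i] is False`` marks a
    not-relevant item; causes default to {cognitive} for any limitation so
    records are strictly valid unless the test overrides them.
    """
    catalog = load_catalog(domain)
    assert len(scores) == len(catalog)
    responses = []
    for i, item in enumerate(catalog):
        rel = True if relevant is None else relevant[i]
        s = scores[i]
        if causes is not None:
            cs = frozenset(causes[i])
        elif s is not None and s >= 1:
            cs = frozenset({Cause.COGNITIVE})
        else:
            cs = frozenset()
        responses.append(ItemResponse(item.item_id, rel, s, cs))
    return Assessment(participant_id, Domain(domain), tuple(responses),
                      report_mode)


@pytest.fixture
def worked_example():
    """Six basic activities: four scored 0, one scored 1 for a cognitive
    reason, one scored 3 for a physical reason."""
    return make_assessment(
        "basic",
        [0, 0, 0, 0, 1, 3],
        causes=[(), (), (), (), (Cause.COGNITIVE,), (Cause.PHYSICAL,)],
    )
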