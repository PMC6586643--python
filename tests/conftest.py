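import pytest

from holopept import PipelineConfig, PrecursorRecord, annotate_precursor
from holopept.reference_data import TOY_PRECURSORS


@pytest.fixture
def toy_annotations():
    """Annotations of the published-fragment toy precursors (provided signals)."""
    out = {}
    for name, toy in TOY_PRECURSORS.items():
        cfg = PipelineConfig(signal_mode="provided",
                             signal_provided_map={name: toy.signal_end},
                             monobasic_mode=toy.monobasic_mode)
        rec = PrecursorRecord(id=name, sequence=toy.sequence)
        out[name] = annotate_precursor(rec, cfg)
    return out
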