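import numpy as np
import pytest

from odrstream.stream_io import AttributeSpec, Instance, StreamSchema, Window


@pytest.fixture
def two_numeric_schema():
    """Two numeric attributes, binary class {a, b}."""
    return StreamSchema(
        (AttributeSpec("x0", "numeric"), AttributeSpec("x1", "numeric")),
        AttributeSpec("class", "nominal", ("a", "b")),
    )


@pytest.fixture
def mixed_schema():
    """Numeric + nominal predictive attributes, 3 classes."""
    return StreamSchema(
        (
            AttributeSpec("temp", "numeric"),
            AttributeSpec("color", "nominal", ("red", "green", "blue")),
        ),
        AttributeSpec("class", "nominal", ("a", "b", "c")),
    )


def make_instances(rows, labels, start_index=0):
    """Build instances from value rows + labels, assigning stream indices."""
    return [
        Instance(values=tuple(row), label=lbl, index=start_index + i)
        for i, (row, lbl) in enumerate(zip(rows, labels))
    ]


def make_window(values, label="a", start=0):
    """Single-attribute window helper: one numeric value per instance."""
    insts = [Instance(values=(float(v),), label=label, index=start + i)
             for i, v in enumerate(values)]
    return Window(insts, start)


@pytest.fixture
def one_attr_schema():
    return StreamSchema(
        (AttributeSpec("x", "numeric"),),
        AttributeSpec("class", "nominal", ("a", "b")),
    )
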