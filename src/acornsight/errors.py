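"""Exception hierarchy for the acorn-screening pipeline."""


class AcornsightError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AcornsightError):
    """Invalid scene or pipeline configuration (geometry, ranges, levels)."""


class GeometryError(AcornsightError):
    """A region (patch, circle, ROI) does not fit inside the raster."""


class DegenerateReferenceError(AcornsightError):
    """Reference patch statistics unusable (zero channel mean)."""


class SegmentationError(AcornsightError):
    """No dark object / no circle satisfying the detection contract."""


class DegenerateMaskError(AcornsightError):
    """Section mask has zero area; averages are undefined."""


class AlignmentError(AcornsightError):
    """Prediction and reference tables do not share the same sequence ids."""

    def __init__(self, missing_in_predictions, missing_in_reference):
        self.missing_in_predictions = sorted(missing_in_predictions)
        self.missing_in_reference = sorted(missing_in_reference)
        super().__init__(
            "sequence_id mismatch: "
            f"missing in predictions {self.missing_in_predictions[:10]}, "
            f"missing in reference {self.missing_in_reference[:10]}"
        )


class PipelineError(AcornsightError):
    """A pipeline stage failed; message carries the stage tag."""
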