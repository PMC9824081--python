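import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from herdtrack.geometry import BoundingBox
from herdtrack.mot_io import Detection, TrackRecord


@pytest.fixture
def box():
    def _make(x=0.0, y=0.0, w=10.0, h=10.0):
        return BoundingBox(x, y, w, h)

    return _make


@pytest.fixture
def walk_detections():
    """Detections of k animals on parallel constant-velocity walks."""

    def _make(k=2, n_frames=50, spacing=400.0, speed=3.0, skip=()):
        dets = []
        for frame in range(1, n_frames + 1):
            for i in range(k):
                if (frame, i) in skip:
                    continue
                dets.append(
                    Detection(
                        frame=frame,
                        box=BoundingBox(
                            50.0 + speed * frame, 50.0 + spacing * i, 60.0, 40.0
                        ),
                    )
                )
        return dets

    return _make


@pytest.fixture
def walk_gt():
    """Ground truth matching walk_detections (ids 1..k)."""

    def _make(k=2, n_frames=50, spacing=400.0, speed=3.0):
        recs = []
        for frame in range(1, n_frames + 1):
            for i in range(k):
                recs.append(
                    TrackRecord(
                        frame=frame,
                        track_id=i + 1,
                        box=BoundingBox(
                            50.0 + speed * frame, 50.0 + spacing * i, 60.0, 40.0
                        ),
                    )
                )
        return recs

    return _make
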