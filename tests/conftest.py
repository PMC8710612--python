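import numpy as np
import pytest

from lonespeech.audio_features import AudioResponse, Segmentation, detect_voice_activity

RATE = 16000


def make_audio(samples, rate=RATE, question_id=1):
    return AudioResponse(samples=np.asarray(samples, dtype=float), rate=rate,
                         question_id=question_id)


def sine(freq, duration_s, rate=RATE, amp=0.5):
    t = np.arange(int(duration_s * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def pulse_train(f0, duration_s, rate=RATE):
    """Impulse train with exact integer period round(rate/f0)."""
    n = int(duration_s * rate)
    x = np.zeros(n)
    period = int(round(rate / f0))
    x[::period] = 1.0
    return x


def vowel(f1, f2, duration_s, f0=120.0, bw1=80.0, bw2=120.0, rate=RATE, seed=0):
    """Source-filter synthesis: pulse train through two known resonators."""
    import scipy.signal

    x = pulse_train(f0, duration_s, rate)
    for f, bw in ((f1, bw1), (f2, bw2)):
        r = np.exp(-np.pi * bw / rate)
        theta = 2 * np.pi * f / rate
        x = scipy.signal.lfilter([1.0], [1.0, -2 * r * np.cos(theta), r * r], x)
    rng = np.random.default_rng(seed)
    x = x + 1e-4 * rng.standard_normal(x.size)
    return 0.9 * x / np.max(np.abs(x))


@pytest.fixture(scope="session")
def voiced_tone():
    """3 s 220 Hz tone: a fully voiced response."""
    audio = make_audio(sine(220, 3.0))
    seg = detect_voice_activity(audio)
    return audio, seg


@pytest.fixture(scope="session")
def vowel_audio():
    """Synthetic vowel with known formants (500, 1500) Hz."""
    audio = make_audio(vowel(500, 1500, 2.0))
    seg = detect_voice_activity(audio)
    return audio, seg
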