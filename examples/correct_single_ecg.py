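"""Correct one hand-measured ECG, starting from paper squares.

A QT of 9.55 small squares and an RR of 15.6 squares at 25 mm/s are
converted to ms / bpm, then corrected by all five methods.
"""

from qtckit import IntervalRecord, correct_all, hr_from_rr_squares, qt_ms_from_squares

qt_ms = qt_ms_from_squares(9.55)   # 1 small square = 40 ms
hr = hr_from_rr_squares(15.6)      # HR = 1500 / RR-in-squares

record = IntervalRecord("demo", ecg_index=1, sex="male", qt_ms=qt_ms, hr_bpm=hr)
corrected = correct_all(record)

print(f"QT  = {qt_ms:.0f} ms, HR = {hr:.1f} bpm")
for method in ("bazett", "fridericia", "framingham", "hodges", "simple"):
    flag = " (prolonged)" if corrected.prolonged(method) else ""
    print(f"QTc {method:<11} = {corrected.qtc(method):6.1f} ms{flag}")

# The five corrections disagree by design: each maps the measured QT to the
# QT expected at 60 bpm under a different QT/rate model.  The simple rule
# (QT + 2(HR-60), minus 10 above 90 bpm) tracks Hodges to within a few ms.
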