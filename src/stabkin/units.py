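"""Unit conversions used at the I/O boundary.

Internally everything runs in days and Kelvin; files carry degrees
Celsius and either days, months or logger hours.
"""

KELVIN_OFFSET = 273.15
DAYS_PER_MONTH = 30.4375  # mean Gregorian month
HOURS_PER_DAY = 24.0


def celsius_to_kelvin(t_c):
    return t_c + KELVIN_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - KELVIN_OFFSET


def months_to_days(t_months):
    return t_months * DAYS_PER_MONTH


def days_to_months(t_days):
    return t_days / DAYS_PER_MONTH


def hours_to_days(t_hours):
    return t_hours / HOURS_PER_DAY
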