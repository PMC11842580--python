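# Decision table of the Combined Drought Indicator.
#
# Columns A..H are the eight combinations of the three exceedance flags
# (spi, sma, fapar) at time T:
#   A=(0,0,0) B=(1,0,0) C=(0,1,0) D=(0,0,1)
#   E=(0,1,1) F=(1,1,0) G=(1,0,1) H=(1,1,1)
# where spi = (SPI-1 < -2) OR (SPI-3 < -1), sma = (SMA <= -1),
# fapar = (FAPAR anomaly <= -1).
#
# Rows are the class at time T-1.  A cell is either a class name
# (unconditional) or an ordered rule list over the sub-condition
# predicates wet_spi    = (SPI-1 > 0.5) AND (SPI-3 > 0)
#            sma_partial   = SMA in (-0.5, 0]
#            fapar_partial = FAPAR anomaly in (-0.5, 0]
# A column given as a single class name applies to every row.
#
# Direct transitions from the drought classes (watch, warning, alert)
# to no_drought are never produced: they are always modulated through
# the recovery classes.

columns:
  A:
    no_drought: no_drought
    watch: recovery
    warning:
      - if: sma_partial
        then: temp_sm_recovery
      - default: recovery
    alert:
      - if: fapar_partial
        then: temp_veg_recovery
      - default: recovery
    recovery: no_drought
    temp_sm_recovery:
      - if: sma_partial
        then: temp_sm_recovery
      - default: no_drought
    temp_veg_recovery:
      - if: fapar_partial
        then: temp_veg_recovery
      - default: no_drought
  B: watch
  C:
    no_drought:
      - if: wet_spi
        then: no_drought
      - default: warning
    watch: warning
    warning: warning
    alert: warning
    recovery:
      - if: wet_spi
        then: no_drought
      - default: warning
    temp_sm_recovery: warning
    temp_veg_recovery: warning
  D:
    no_drought: no_drought
    watch: watch
    warning: warning
    alert: alert
    recovery: recovery
    temp_sm_recovery: temp_sm_recovery
    temp_veg_recovery: temp_veg_recovery
  E: alert
  F: warning
  G: alert
  H: alert
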