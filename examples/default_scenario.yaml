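regions:
- NMM
- RRD
- NCC
- CH
- SE
- MKD
year_start: 1975
year_end: 2019
baseline: 1.063
ar1:
  rho: 0.5
  sigma_eps: 0.006
delta:
  NMM: 1
  RRD: 1
  NCC: 1
  CH: 0
  SE: 1
  MKD: 0
trapezoids:
  NMM:
    gamma: 2001.5
    lambda1: 15.0
    lambda2: 3.0
    lambda3: 18.0
    xi: 0.069
  RRD:
    gamma: 2001.0
    lambda1: 12.0
    lambda2: 4.0
    lambda3: 18.0
    xi: 0.083
  NCC:
    gamma: 2001.5
    lambda1: 14.0
    lambda2: 4.0
    lambda3: 17.0
    xi: 0.054
  CH:
    gamma: 2001.0
    lambda1: 13.0
    lambda2: 5.0
    lambda3: 18.0
    xi: 0.0
  SE:
    gamma: 2000.5
    lambda1: 12.0
    lambda2: 5.0
    lambda3: 17.0
    xi: 0.059
  MKD:
    gamma: 2001.0
    lambda1: 13.0
    lambda2: 5.0
    lambda3: 18.0
    xi: 0.0
sources:
- name: 1989 Census
  source_type: census
  survey_year: 1989
  years:
  - 1988
  births_per_region_year: 13000
  fractional_offset: 0.5
  report_sampling_se: true
  design_effect: 1.0
- name: 1999 Census
  source_type: census
  survey_year: 1999
  years:
  - 1998
  births_per_region_year: 6500
  fractional_offset: 0.5
  report_sampling_se: true
  design_effect: 1.0
- name: 2009 Census
  source_type: census
  survey_year: 2009
  years:
  - 2008
  births_per_region_year: 44000
  fractional_offset: 0.5
  report_sampling_se: true
  design_effect: 1.0
- name: 2019 Census
  source_type: census
  survey_year: 2019
  years:
  - 2018
  births_per_region_year: 230000
  fractional_offset: 0.5
  report_sampling_se: true
  design_effect: 1.0
- name: 1997 Retrospective Survey
  source_type: retrospective_survey
  survey_year: 1997
  years:
  - 1975
  - 1976
  - 1977
  - 1978
  - 1979
  - 1980
  - 1981
  - 1982
  - 1983
  - 1984
  - 1985
  - 1986
  - 1987
  - 1988
  - 1989
  - 1990
  - 1991
  - 1992
  - 1993
  - 1994
  - 1995
  - 1996
  births_per_region_year: 150
  fractional_offset: 0.0
  report_sampling_se: true
  design_effect: 1.0
- name: 2002 Retrospective Survey
  source_type: retrospective_survey
  survey_year: 2002
  years:
  - 1978
  - 1979
  - 1980
  - 1981
  - 1982
  - 1983
  - 1984
  - 1985
  - 1986
  - 1987
  - 1988
  - 1989
  - 1990
  - 1991
  - 1992
  - 1993
  - 1994
  - 1995
  - 1996
  - 1997
  - 1998
  - 1999
  - 2000
  - 2001
  births_per_region_year: 140
  fractional_offset: 0.0
  report_sampling_se: true
  design_effect: 1.0
- name: 2014 Retrospective Survey
  source_type: retrospective_survey
  survey_year: 2014
  years:
  - 1990
  - 1991
  - 1992
  - 1993
  - 1994
  - 1995
  - 1996
  - 1997
  - 1998
  - 1999
  - 2000
  - 2001
  - 2002
  - 2003
  - 2004
  - 2005
  - 2006
  - 2007
  - 2008
  - 2009
  - 2010
  - 2011
  - 2012
  - 2013
  births_per_region_year: 500
  fractional_offset: 0.0
  report_sampling_se: true
  design_effect: 1.0
- name: 2006 Annual Survey
  source_type: annual_survey
  survey_year: 2006
  years:
  - 2005
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2007 Annual Survey
  source_type: annual_survey
  survey_year: 2007
  years:
  - 2006
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2008 Annual Survey
  source_type: annual_survey
  survey_year: 2008
  years:
  - 2007
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2009 Annual Survey
  source_type: annual_survey
  survey_year: 2009
  years:
  - 2008
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2010 Annual Survey
  source_type: annual_survey
  survey_year: 2010
  years:
  - 2009
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2011 Annual Survey
  source_type: annual_survey
  survey_year: 2011
  years:
  - 2010
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2012 Annual Survey
  source_type: annual_survey
  survey_year: 2012
  years:
  - 2011
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2013 Annual Survey
  source_type: annual_survey
  survey_year: 2013
  years:
  - 2012
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2014 Annual Survey
  source_type: annual_survey
  survey_year: 2014
  years:
  - 2013
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2015 Annual Survey
  source_type: annual_survey
  survey_year: 2015
  years:
  - 2014
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2016 Annual Survey
  source_type: annual_survey
  survey_year: 2016
  years:
  - 2015
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2017 Annual Survey
  source_type: annual_survey
  survey_year: 2017
  years:
  - 2016
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2018 Annual Survey
  source_type: annual_survey
  survey_year: 2018
  years:
  - 2017
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
- name: 2019 Annual Survey
  source_type: annual_survey
  survey_year: 2019
  years:
  - 2018
  births_per_region_year: 3500
  fractional_offset: 0.5
  report_sampling_se: false
  design_effect: 1.0
seed: 0
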