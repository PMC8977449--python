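study_id,country,treatment,role,n,outcome_id,followup_weeks,kind,events,mean_change,sd,scale_name,direction,risk_of_bias
Nct2012,UK,cannabinoids,intervention,56,,7,,,,,NRS,higher_is_worse,high
Nct2012,UK,placebo,comparison,60,,7,,,,,NRS,higher_is_worse,high
Cardenas2013,USA,pregabalin,intervention,111,,16,,,,,NRS,higher_is_worse,high
Cardenas2013,USA,placebo,comparison,108,,16,,,,,NRS,higher_is_worse,high
Agarwal2017,India,amitriptyline,intervention,74,,3,,,,,SFMPQ2,higher_is_worse,high
Agarwal2017,India,lamotrigine,comparison,73,,3,,,,,SFMPQ2,higher_is_worse,high
Amr2010,Egypt,ketamine,intervention,20,,4,,,,,VAS-100,higher_is_worse,moderate
Amr2010,Egypt,gabapentin,comparison,20,,4,,,,,VAS-100,higher_is_worse,moderate
Amr2011,Egypt,ketamine,intervention,20,,8,,,,,VAS-100,higher_is_worse,moderate
Amr2011,Egypt,gabapentin,comparison,20,,8,,,,,VAS-100,higher_is_worse,moderate
Andresen2016,Denmark,cannabinoids,intervention,36,,12,,,,,NRS,higher_is_worse,moderate
Andresen2016,Denmark,placebo,comparison,37,,12,,,,,NRS,higher_is_worse,moderate
Salinas2012,Colombia,carbamazepine,intervention,24,,24,,,,,VAS-100,higher_is_worse,high
Salinas2012,Colombia,placebo,comparison,22,,24,,,,,VAS-100,higher_is_worse,high
Siddall2006,Australia,pregabalin,intervention,70,,12,,,,,NRS,higher_is_worse,high
Siddall2006,Australia,placebo,comparison,67,,12,,,,,NRS,higher_is_worse,high
Tai2016,USA,gabapentin,intervention,7,,10,,,,,NPS,higher_is_worse,moderate
Tai2016,USA,placebo,comparison,7,,10,,,,,NPS,higher_is_worse,moderate
Vranken2008,Netherlands,pregabalin,intervention,20,,4,,,,,VAS-10,higher_is_worse,moderate
Vranken2008,Netherlands,placebo,comparison,20,,4,,,,,VAS-10,higher_is_worse,moderate
Vranken2011,Netherlands,duloxetine,intervention,18,,8,,,,,VAS-10,higher_is_worse,high
Vranken2011,Netherlands,placebo,comparison,18,,8,,,,,VAS-10,higher_is_worse,high
Yilmaz2015,Turkey,pregabalin,intervention,15,,18,,,,,VAS-10,higher_is_worse,moderate
Yilmaz2015,Turkey,gabapentin,comparison,15,,18,,,,,VAS-10,higher_is_worse,moderate
Chun2019,USA,BTX-A,intervention,5,,12,,,,,NPRS,higher_is_worse,moderate
Chun2019,USA,placebo,comparison,3,,12,,,,,NPRS,higher_is_worse,moderate
Finnerup2009,Denmark,levetiracetam,intervention,18,,5,,,,,NRS,higher_is_worse,high
Finnerup2009,Denmark,placebo,comparison,18,,5,,,,,NRS,higher_is_worse,high
Han2016,Korea,BTX-A,intervention,20,,8,,,,,VAS-100,higher_is_worse,high
Han2016,Korea,placebo,comparison,20,,8,,,,,VAS-100,higher_is_worse,high
Kaydok2014,Turkey,gabapentin,intervention,14,,4,,,,,VAS-100,higher_is_worse,moderate
Kaydok2014,Turkey,pregabalin,comparison,14,,4,,,,,VAS-100,higher_is_worse,moderate
Levendoglu2004,Turkey,gabapentin,intervention,10,,8,,,,,VAS-100,higher_is_worse,moderate
Levendoglu2004,Turkey,placebo,comparison,10,,8,,,,,VAS-100,higher_is_worse,moderate
Norrbrink2009,Sweden,tramadol,intervention,23,,4,,,,,MPI,higher_is_worse,high
Norrbrink2009,Sweden,placebo,comparison,12,,4,,,,,MPI,higher_is_worse,high
Rintala2007,USA,amitriptyline,intervention,28,,8,,,,,VAS-NRS,higher_is_worse,moderate
Rintala2007,USA,gabapentin,intervention,26,,8,,,,,VAS-NRS,higher_is_worse,moderate
Rintala2007,USA,placebo,comparison,25,,8,,,,,VAS-NRS,higher_is_worse,moderate
Rintala2010,USA,cannabinoids,intervention,7,,4,,,,,NRS,higher_is_worse,moderate
Rintala2010,USA,placebo,comparison,7,,4,,,,,NRS,higher_is_worse,moderate
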