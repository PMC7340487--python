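indicator_id,name,topic,direction,transform,target_type,target_value,baseline_year,target_year,units,assumed
2.2.1,Prevalence of stunting in children under 5 years,child_nutrition,lower_better,linear,relative_reduction,0.40,2015,2025,percent,1
2.2.2a,Prevalence of wasting in children under 5 years,child_nutrition,lower_better,linear,absolute,5,,2025,percent,0
2.2.2b,Prevalence of overweight in children aged 2-4 years,child_nutrition,lower_better,linear,no_increase,,2015,2025,percent,0
3.1.1,Maternal mortality ratio,mchrh,lower_better,log,absolute,70,,2030,per 100000 live births,0
3.1.2,Births attended by skilled health personnel,mchrh,higher_better,logit,absolute,0.99,,2030,proportion,1
3.2.1,Under-5 mortality rate,mchrh,lower_better,log,absolute,25,,2030,per 1000 live births,0
3.2.2,Neonatal mortality rate,mchrh,lower_better,log,absolute,12,,2030,per 1000 live births,0
3.b.1,Coverage of eight vaccines in target populations,mchrh,higher_better,logit,absolute,0.99,,2030,proportion,1
3.7.1,Family planning need satisfied with modern methods,mchrh,higher_better,logit,absolute,0.99,,2030,proportion,1
3.3.1,Age-standardised rate of new HIV infections,infectious,lower_better,log,relative_reduction,0.90,2010,2030,per 1000,0
3.3.2,Age-standardised rate of new TB cases,infectious,lower_better,log,relative_reduction,0.80,2015,2030,per 100000,0
3.3.3,Age-standardised rate of malaria cases,infectious,lower_better,log,relative_reduction,0.90,2015,2030,per 1000,0
3.3.4,Age-standardised rate of hepatitis B incidence,infectious,lower_better,log,relative_reduction,0.95,2015,2030,per 100000,0
3.3.5,Age-standardised prevalence of 15 NTDs,infectious,lower_better,linear,relative_reduction,0.90,2015,2030,percent,1
3.4.1,Premature mortality from four major NCDs ages 30-70,ncd_mortality,lower_better,log,relative_reduction,0.3333333333,2015,2030,per 100000,0
3.4.2,Age-standardised suicide mortality,ncd_mortality,lower_better,log,relative_reduction,0.3333333333,2015,2030,per 100000,0
3.5.2,Risk-weighted prevalence of alcohol use (SEV),ncd_risk,lower_better,linear,relative_reduction,0.10,2015,2025,percent,1
3.a.1,Age-standardised prevalence of daily smoking ages 10+,ncd_risk,lower_better,linear,relative_reduction,0.30,2015,2025,percent,1
3.6.1,Age-standardised road injury mortality,road_injury,lower_better,log,relative_reduction,0.50,2015,2020,per 100000,1
3.9.1,Mortality attributable to air pollution,env_outcome,lower_better,log,relative_reduction,0.90,2015,2030,per 100000,1
3.9.2,Mortality attributable to unsafe WaSH,env_outcome,lower_better,log,relative_reduction,0.90,2015,2030,per 100000,1
3.9.3,Mortality from unintentional poisonings,env_outcome,lower_better,log,relative_reduction,0.90,2015,2030,per 100000,1
6.1.1,Risk-weighted prevalence of unsafe water (SEV),env_exposure,lower_better,linear,elimination,0,,2030,percent,1
6.2.1a,Risk-weighted prevalence of unsafe sanitation (SEV),env_exposure,lower_better,linear,elimination,0,,2030,percent,1
6.2.1b,Risk-weighted prevalence of unsafe hygiene (SEV),env_exposure,lower_better,linear,elimination,0,,2030,percent,1
7.1.2,Risk-weighted prevalence of household air pollution (SEV),env_exposure,lower_better,linear,elimination,0,,2030,percent,1
11.6.2,Population-weighted mean PM2.5,env_exposure,lower_better,linear,absolute,10,,2030,ug/m3,0
3.8.1,UHC essential service coverage index,uhc,higher_better,linear,absolute,100,,2030,index 0-100,1
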